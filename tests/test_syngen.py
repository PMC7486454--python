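"""Generator contracts: construction, determinism, calibration, truth."""

import numpy as np
import pytest

from rediplo._codon import STOP_CODONS
from rediplo.syngen import (
    SimulationConfig,
    TEFamily,
    apply_wgd_and_evolve,
    evolve_cds,
    insert_transposons,
    simulate,
    simulate_ancestral_genome,
    simulate_population_snps,
)

from conftest import SMALL_FAMS, small_config


def test_ancestral_construction_contract():
    cfg = SimulationConfig(seed=1, n_contigs=2, contig_len=100_000,
                           n_genes_per_contig=10, te_families=())
    seqs, genes = simulate_ancestral_genome(cfg)
    assert len(seqs) == 2
    assert all(len(s) == 100_000 for s in seqs.values())
    assert len(genes) == 20
    for g in genes:
        cds = g.cds(seqs)
        assert len(cds) % 3 == 0
        assert cds.startswith("ATG")
        assert cds[-3:] in STOP_CODONS
        internal = {cds[i:i + 3] for i in range(3, len(cds) - 3, 3)}
        assert not internal & STOP_CODONS
    # genes do not overlap
    by_ctg = {}
    for g in genes:
        by_ctg.setdefault(g.contig, []).append((g.start, g.end))
    for ivs in by_ctg.values():
        ivs.sort()
        assert all(a_end <= b_start for (_, a_end), (b_start, _)
                   in zip(ivs, ivs[1:]))


def test_sizing_error_when_genes_cannot_fit():
    cfg = SimulationConfig(seed=1, n_contigs=1, contig_len=10_000,
                           n_genes_per_contig=10)
    with pytest.raises(ValueError, match="cannot fit"):
        cfg.validate()


def test_determinism_byte_identical(tmp_path):
    from rediplo.syngen import write_all

    cfg = small_config(seed=9, n_contigs=1, contig_len=60_000,
                       n_genes_per_contig=8,
                       te_families=(TEFamily("Tc1", "DNA", 400, 12, 3e6),))
    d1 = simulate(cfg)
    d2 = simulate(small_config(seed=9, n_contigs=1, contig_len=60_000,
                               n_genes_per_contig=8,
                               te_families=(TEFamily("Tc1", "DNA", 400, 12, 3e6),)))
    p1 = write_all(d1, tmp_path / "a")
    p2 = write_all(d2, tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_gc_content_within_binomial_interval():
    cfg = SimulationConfig(seed=2, n_contigs=1, contig_len=1_000_000,
                           n_genes_per_contig=0, gc_content=0.5,
                           te_families=())
    seqs, _ = simulate_ancestral_genome(cfg)
    s = seqs["ctg01"]
    gc = (s.count("G") + s.count("C")) / len(s)
    assert 0.49 <= gc <= 0.51


def test_zero_divergence_copies_identical():
    cfg = small_config(seed=3, divergence_time=0.0, te_families=())
    ds = simulate(cfg)
    for contig in ds.ancestral_sequences:
        assert ds.sequences[f"{contig}_R1"] == ds.sequences[f"{contig}_R2"]


def test_omega_zero_gives_no_nonsynonymous_changes(rng):
    from Bio.Seq import Seq

    from rediplo.syngen import _random_cds

    for _ in range(20):
        cds = _random_cds(200, rng)
        evolved, n_syn, n_nonsyn = evolve_cds(cds, 0.02, 0.0, 2.0, rng)
        assert n_nonsyn == 0
        assert str(Seq(cds).translate()) == str(Seq(evolved).translate())


def test_synonymous_calibration_direct_count_oracle():
    """Realized synonymous divergence across ≥500 gene pairs must sit within
    3 SE of 2·r·T, the oracle being the generator's own count of introduced
    synonymous changes."""
    cfg = SimulationConfig(seed=4, n_contigs=5, contig_len=250_000,
                           n_genes_per_contig=110, utr_len=100,
                           te_families=())
    seqs, genes = simulate_ancestral_genome(cfg)
    _, _, truth = apply_wgd_and_evolve(seqs, genes, cfg,
                                       np.random.default_rng(4))
    props = np.array([n / S for n, S in truth.syn_changes.values()])
    assert len(props) >= 500
    se = props.std(ddof=1) / np.sqrt(len(props))
    assert abs(props.mean() - cfg.expected_ks) < 3 * se


def test_te_indel_fraction_one_forces_all_te():
    cfg = small_config(seed=5, te_indel_fraction=1.0)
    ds = simulate(cfg)
    assert len(ds.truth.non_te_indels) == 0
    assert len(ds.truth.te_insertions) == sum(f.copy_count for f in SMALL_FAMS)
    # every simulated insertion appears in the emitted TE annotation
    ann = {(r.contig, r.start, r.end) for r in ds.te_table.itertuples(index=False)}
    for t in ds.truth.te_insertions:
        assert (t["contig"], t["start"], t["end"]) in ann


def test_ta_preference_one_all_breakpoints_ta():
    cfg = small_config(seed=6, ta_preference=1.0, cds_insertion_prob=1.0)
    ds = simulate(cfg)
    indels = ds.truth.te_insertions + ds.truth.non_te_indels
    for t in indels:
        seq = ds.sequences[t["contig"]]
        s = t["start"]
        e = s + t["length"]
        assert seq[s - 1] == "T" and seq[e] == "A", t


def test_ta_preference_default_within_binomial_interval():
    fams = (TEFamily("mini", "DNA", 120, 1000, 3e6),)
    cfg = SimulationConfig(seed=8, n_contigs=1, contig_len=300_000,
                           n_genes_per_contig=0, te_families=fams,
                           te_indel_fraction=1.0, ta_preference=0.8)
    ds = simulate(cfg)
    hits = 0
    n = 0
    for t in ds.truth.te_insertions:
        seq = ds.sequences[t["contig"]]
        s, e = t["start"], t["start"] + t["length"]
        if 0 < s and e < len(seq):
            n += 1
            hits += seq[s - 1] == "T" and seq[e] == "A"
    assert n >= 900
    assert 0.76 <= hits / n <= 0.84


def test_contig_length_conservation(small_sim):
    anc = {c: len(s) for c, s in small_sim.ancestral_sequences.items()}
    for contig, L in small_sim.contig_lengths.items():
        base = anc[contig.rsplit("_", 1)[0]]
        ins = sum(t["length"] for t in small_sim.truth.te_insertions
                  if t["contig"] == contig)
        ins += sum(t["length"] for t in small_sim.truth.non_te_indels
                   if t["contig"] == contig)
        assert L == base + ins


def test_snp_null_multiplier_one():
    cfg = small_config(seed=12, hypermut_multiplier=1.0)
    ds = simulate(cfg)
    inside = outside = 0
    len_in = len_out = 0
    for contig, L in ds.contig_lengths.items():
        pos = np.sort(ds.snps.loc[ds.snps.contig == contig, "pos"].to_numpy())
        ivs = ds.truth.hypermut_intervals.get(contig, [])
        li = sum(e - s for s, e in ivs)
        ni = sum(int(np.searchsorted(pos, e) - np.searchsorted(pos, s))
                 for s, e in ivs)
        inside += ni
        outside += len(pos) - ni
        len_in += li
        len_out += L - li
    d_in = inside / len_in * 1000
    d_out = outside / len_out * 1000
    se = np.sqrt(inside) / len_in * 1000 + np.sqrt(outside) / len_out * 1000
    assert abs(d_in - d_out) < 3 * se


def test_snp_rate_elevated_inside_hot_zones(small_sim):
    cfg = small_sim.config
    inside = 0
    len_in = 0
    for contig in small_sim.contig_lengths:
        pos = np.sort(small_sim.snps.loc[small_sim.snps.contig == contig,
                                         "pos"].to_numpy())
        for s, e in small_sim.truth.hypermut_intervals.get(contig, []):
            inside += int(np.searchsorted(pos, e) - np.searchsorted(pos, s))
            len_in += e - s
    d_in = inside / len_in * 1000
    expected = cfg.snp_rate_per_kb * cfg.hypermut_multiplier
    assert abs(d_in - expected) < 3 * np.sqrt(inside) / len_in * 1000


def test_empty_hypermut_set_uniform_density(rng):
    cfg = small_config(seed=13)
    seqs = {"c1": "ACGT" * 25_000}
    snps = simulate_population_snps(seqs, {}, cfg, rng)
    # split the contig in halves: densities agree within Poisson noise
    pos = snps["pos"].to_numpy()
    left = int((pos < 50_000).sum())
    right = len(pos) - left
    assert abs(left - right) < 3 * np.sqrt(left + right)


def test_expression_nonnegative_and_effects_recorded(small_sim):
    assert (small_sim.expression.to_numpy() >= 0).all()
    assert set(small_sim.expression.index) == {g.gene_id for g in small_sim.genes}
    assert len(small_sim.truth.expression_effects) == len(small_sim.genes)


def test_expected_ks_identity():
    cfg = small_config()
    assert cfg.expected_ks == pytest.approx(2 * cfg.syn_rate * cfg.divergence_time)
    assert cfg.expected_ks == pytest.approx(0.0086346)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(te_indel_fraction=1.5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(cds_len=1000).validate()
    with pytest.raises(ValueError):
        SimulationConfig(hypermut_multiplier=0.5).validate()
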