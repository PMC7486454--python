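"""Seed-chain alignment, contig pairing, ohnolog calling, PAF round-trip."""

import numpy as np
import pytest

from rediplo.homeopair import (
    HSP,
    assert_colinear,
    call_ohnologs,
    duplicate_retention_percent,
    pair_contigs,
    read_paf,
    seed_and_chain,
    write_paf,
)
from rediplo.syngen import SimulationConfig, simulate


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_identical_contigs_single_full_chain(rng):
    seq = _random_seq(rng, 10_000)
    hsps = seed_and_chain({"A": seq, "B": seq})
    assert len(hsps) == 1
    h = hsps[0]
    assert h.identity == 100.0
    assert h.aligned_length >= 0.99 * len(seq)


def test_disjoint_sequences_no_hsps(rng):
    a = _random_seq(rng, 20_000)
    b = _random_seq(rng, 20_000)
    assert seed_and_chain({"A": a, "B": b}) == []


def test_short_contig_skipped_with_warning(rng):
    with pytest.warns(UserWarning, match="shorter than k"):
        hsps = seed_and_chain({"A": "ACGTACGT", "B": _random_seq(rng, 5000)})
    assert hsps == []


def test_k_below_minimum_rejected(rng):
    with pytest.raises(ValueError):
        seed_and_chain({"A": "ACGT" * 100}, k=9)


def test_chain_identity_matches_global_alignment_oracle(rng):
    """On a substitution-only pair the chain identity must match full
    Needleman-Wunsch identity to within 0.5 percentage points."""
    from Bio import Align

    seq = _random_seq(rng, 6000)
    arr = list(seq)
    idx = rng.choice(len(arr), size=int(0.02 * len(arr)), replace=False)
    for i in idx:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    mutated = "".join(arr)
    hsps = seed_and_chain({"A": seq, "B": mutated})
    chain_identity = (100 * sum(h.matches for h in hsps)
                      / sum(h.aligned_length for h in hsps))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aln = aligner.align(seq, mutated)[0]
    nw_identity = 100 * aln.counts().identities / aln.length
    assert chain_identity == pytest.approx(nw_identity, abs=0.5)


def test_reverse_strand_homeology_detected(rng):
    seq = _random_seq(rng, 8000)
    comp = str.maketrans("ACGT", "TGCA")
    rc = seq.translate(comp)[::-1]
    hsps = seed_and_chain({"A": seq, "B": rc})
    assert hsps
    assert all(h.strand == "-" for h in hsps)
    assert sum(h.aligned_length for h in hsps) >= 0.99 * len(seq)


def test_true_contig_pairs_recovered(small_sim, small_pairings):
    expected = {(f"{c}_R1", f"{c}_R2") for c in small_sim.ancestral_sequences}
    got = {(p.contig_a, p.contig_b) for p in small_pairings}
    assert got == expected
    for p in small_pairings:
        assert_colinear(p)
        assert p.coverage_a > 0.5 and p.coverage_b > 0.5


def test_contig_without_hsps_unpaired(rng):
    seq = _random_seq(rng, 20_000)
    lone = _random_seq(rng, 20_000)
    hsps = seed_and_chain({"A": seq, "B": seq, "C": lone})
    pairings = pair_contigs(hsps, {"A": len(seq), "B": len(seq),
                                   "C": len(lone)})
    contigs = {p.contig_a for p in pairings} | {p.contig_b for p in pairings}
    assert "C" not in contigs
    assert contigs == {"A", "B"}


def test_three_way_tie_breaks_lexicographically(rng):
    seq = _random_seq(rng, 15_000)
    # A is identical to both B and C; reciprocal-best must settle on B
    hsps = seed_and_chain({"A": seq, "B": seq, "C": seq})
    pairings = pair_contigs(hsps, {n: len(seq) for n in "ABC"})
    assert len(pairings) == 1
    assert (pairings[0].contig_a, pairings[0].contig_b) == ("A", "B")


def test_zero_divergence_full_ohnolog_recall():
    cfg = SimulationConfig(seed=21, n_contigs=2, contig_len=120_000,
                           n_genes_per_contig=12, divergence_time=0.0,
                           te_families=())
    ds = simulate(cfg)
    pairings = pair_contigs(seed_and_chain(ds.sequences), ds.contig_lengths)
    pairs, _ = call_ohnologs(pairings, ds.genes, ds.sequences)
    found = {(p.gene_a, p.gene_b) for p in pairs}
    found |= {(b, a) for a, b in found}
    assert all(item in found for item in ds.truth.ohnolog_map.items())
    assert all(p.anchor_identity == 100.0 for p in pairs)


def test_ohnolog_recovery_on_default_style_genome(small_sim, small_pairings,
                                                  small_ohnologs):
    pairs, _ = small_ohnologs
    truth = small_sim.truth.ohnolog_map
    found = {(p.gene_a, p.gene_b) for p in pairs}
    found |= {(b, a) for a, b in found}
    n_rec = sum(1 for item in truth.items() if item in found)
    assert n_rec / len(truth) >= 0.95
    assert (len(pairs) - n_rec) / max(len(pairs), 1) <= 0.01


def test_deleted_gene_reported_as_singleton(small_sim, small_pairings):
    genes = list(small_sim.genes)
    victim = next(g for g in genes if g.gene_id.endswith("_R2"))
    partner = victim.gene_id.replace("_R2", "_R1")
    reduced = [g for g in genes if g.gene_id != victim.gene_id]
    pairs, singletons = call_ohnologs(small_pairings, reduced,
                                      small_sim.sequences)
    assert partner in singletons
    assert victim.gene_id not in {p.gene_b for p in pairs}


def test_paf_round_trip(tmp_path):
    hsps = [
        HSP("ctgA", 10, 510, "ctgB", 20, 520, "+", 99.4, 500, 497),
        HSP("ctgA", 1000, 1800, "ctgB", 1100, 1900, "-", 97.25, 800, 778),
    ]
    path = tmp_path / "out.paf"
    write_paf(hsps, {"ctgA": 5000, "ctgB": 6000}, path)
    text = path.read_text().splitlines()
    assert len(text) == 2
    f = text[0].split("\t")
    assert (f[2], f[3]) == ("10", "510")  # 0-based half-open
    back, lengths = read_paf(path)
    assert back == hsps
    assert lengths == {"ctgA": 5000, "ctgB": 6000}


def test_paf_empty(tmp_path):
    path = tmp_path / "empty.paf"
    write_paf([], {}, path)
    assert path.read_text() == ""
    assert read_paf(path) == ([], {})


def test_duplicate_retention_arithmetic():
    assert duplicate_retention_percent(8, 20) == 80.0
    with pytest.raises(ValueError):
        duplicate_retention_percent(1, 0)
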