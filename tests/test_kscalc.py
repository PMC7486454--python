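"""Ka/Ks, 4DTv, Ks-mode dating and the selection scan."""

import math

import numpy as np
import pytest

from rediplo.kscalc import (
    InternalStopError,
    align_codons,
    compute_4dtv,
    date_divergence,
    kaks_selection_scan,
    ks_from_cds_pairs,
    ks_mode,
    ng86,
)
from rediplo.syngen import _random_cds, evolve_cds


def test_align_identical_cds():
    cds = "ATG" + "GGT" * 50 + "TAA"
    aln = align_codons(cds, cds)
    assert aln.n_usable == 51  # stop codon stripped
    assert aln.codons_a == aln.codons_b
    est = ng86(aln)
    assert est.Sd == est.Nd == 0
    assert est.ks == est.ka == 0
    assert est.S + est.N == pytest.approx(3 * aln.n_usable)


def test_align_with_inserted_codon():
    base = "ATG" + "CGT" * 30 + "TAA"
    # insert one extra codon in the middle of b
    mid = 3 + 45
    other = base[:mid] + "TGG" + base[mid:]
    aln = align_codons(base, other)
    assert aln.n_usable == len(base) // 3 - 1  # minus the stop
    assert aln.n_gapped_columns == 1


def test_align_rejects_internal_stop():
    bad = "ATG" + "TAA" + "GGT" * 10 + "TAA"
    with pytest.raises(InternalStopError):
        align_codons(bad, bad)


def test_align_backmap_consistent_with_protein_alignment(rng):
    """Back-mapped codon columns must translate to the aligned residues."""
    from Bio.Seq import Seq

    cds = _random_cds(120, rng)
    arr = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    # remove 5 scattered internal codons from one copy
    drop = sorted(rng.choice(np.arange(2, 115), size=5, replace=False))[::-1]
    arr_b = list(arr)
    for d in drop:
        del arr_b[d]
    aln = align_codons("".join(arr), "".join(arr_b))
    assert aln.n_usable == 119 - 5  # all shared codons, stop stripped
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        assert str(Seq(ca).translate()) == str(Seq(cb).translate())


def test_site_conservation_property(rng):
    for _ in range(5):
        cds = _random_cds(80, rng)
        a, *_ = evolve_cds(cds, 0.05, 0.5, 2.0, rng)
        b, *_ = evolve_cds(cds, 0.05, 0.5, 2.0, rng)
        aln = align_codons(a, b)
        est = ng86(aln)
        assert est.S + est.N == pytest.approx(3 * aln.n_usable)


def test_ng86_agrees_with_independent_implementation(rng):
    """Cross-check dN/dS against Biopython's NG86 (an implementation the
    package does not use internally)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    cds = _random_cds(300, rng)
    a, *_ = evolve_cds(cds, 0.05, 0.3, 2.0, rng)
    b, *_ = evolve_cds(cds, 0.05, 0.3, 2.0, rng)
    est = ng86(align_codons(a, b))
    dn, ds = cal_dn_ds(CodonSeq(a[:-3]), CodonSeq(b[:-3]), method="NG86")
    assert est.ks == pytest.approx(ds, rel=1e-6)
    assert est.ka == pytest.approx(dn, rel=1e-6)


@pytest.mark.parametrize("codon_a,codon_b,n4d,tv", [
    ("GGA", "GGT", 1, 1.0),   # A<->T transversion at a Gly 4D site
    ("GGA", "GGG", 1, 0.0),   # transition
    ("AAA", "AAT", 0, None),  # Lys third position is not fourfold
    ("GGA", "GCA", 0, None),  # first-two mismatch: site ineligible
])
def test_4dtv_single_codon_cases(codon_a, codon_b, n4d, tv):
    prefix = "ATGGTT"  # ATG + Val codon, keeps alignment trivial
    aln = align_codons(prefix + codon_a, prefix + codon_b)
    fourdtv, n = compute_4dtv(aln)
    # the GTT codon is itself a 4D site with no difference
    assert n == n4d + 1
    if tv is None:
        assert fourdtv == pytest.approx(0.0)
    else:
        assert fourdtv == pytest.approx(tv / (n4d + 1))


def test_4dtv_identical_sequences():
    cds = "ATG" + "GGC" * 20 + "TAA"
    fourdtv, n = compute_4dtv(align_codons(cds, cds))
    assert n == 20
    assert fourdtv == 0.0


def test_ks_mode_degenerate_and_bimodal():
    assert ks_mode([0.01] * 50) == pytest.approx(0.01)
    vals = np.concatenate([np.full(900, 0.01), np.full(100, 0.2)])
    vals = vals + np.random.default_rng(0).normal(0, 0.001, 1000)
    mode = ks_mode(vals)
    assert abs(mode - 0.01) < 0.005
    with pytest.raises(ValueError, match="median"):
        ks_mode([0.01] * 10)


def test_date_divergence_formula():
    assert date_divergence(0.0086, 3.51e-9).time_mya == pytest.approx(1.23)
    assert date_divergence(0.0, 3.51e-9).time_mya == 0.0
    assert date_divergence(0.101, 3.51e-9).time_mya == pytest.approx(14.39)
    with pytest.raises(ValueError):
        date_divergence(0.01, 0.0)


def test_date_divergence_linear_in_mode_inverse_in_rate():
    base = date_divergence(0.01, 3.51e-9).time_years
    assert date_divergence(0.02, 3.51e-9).time_years == pytest.approx(2 * base)
    assert date_divergence(0.01, 2 * 3.51e-9).time_years == pytest.approx(base / 2)


def test_ks_unbiased_over_simulated_pairs(rng):
    """Mean NG86 Ks across simulated pairs within 3 SE of the generator's
    expected_ks (2rT)."""
    bl = 3.51e-9 * 1.23e6
    tuples = []
    for i in range(200):
        cds = _random_cds(500, rng)
        a, *_ = evolve_cds(cds, bl, 0.2, 2.0, rng)
        b, *_ = evolve_cds(cds, bl, 0.2, 2.0, rng)
        tuples.append((f"a{i}", f"b{i}", a, b))
    df = ks_from_cds_pairs(tuples)
    ks = df.loc[df["defined"].astype(bool), "ks"].to_numpy()
    se = ks.std(ddof=1) / np.sqrt(len(ks))
    assert abs(ks.mean() - 2 * bl) < 3 * se


def test_selection_scan_null_and_power(rng):
    tuples = []
    for i in range(120):
        cds = _random_cds(500, rng)
        omega = 3.0 if i < 20 else 0.2
        a, *_ = evolve_cds(cds, 0.05, omega, 2.0, rng)
        b, *_ = evolve_cds(cds, 0.05, omega, 2.0, rng)
        tuples.append((f"a{i}", f"b{i}", a, b))
    scan = kaks_selection_scan(ks_from_cds_pairs(tuples), alpha=0.05)
    selected = set(scan.loc[scan["selected"], "gene_a"])
    recall = sum(1 for i in range(20) if f"a{i}" in selected) / 20
    false = sum(1 for i in range(20, 120) if f"a{i}" in selected)
    assert recall >= 0.5
    assert false <= 0.05 * 100 + 3  # type-I control with slack
    assert {"p_fisher", "fdr"} <= set(scan.columns)


def test_selection_scan_zero_differences_not_selected():
    cds = "ATG" + "GCT" * 100 + "TAA"
    scan = kaks_selection_scan(ks_from_cds_pairs([("a", "b", cds, cds)]))
    assert not scan["selected"].any()


def test_ks_infinite_ratio_still_tested():
    est = ks_from_cds_pairs([("a", "b",
                              "ATG" + "GCT" * 50 + "TAA",
                              "ATG" + "GAT" + "GCT" * 49 + "TAA")])
    row = est.iloc[0]
    assert row["ks"] == 0 and row["ka"] > 0
    assert math.isinf(row["omega"])
    scan = kaks_selection_scan(est)
    assert np.isfinite(scan["p_fisher"]).all()
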