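"""Indel extraction, TE classification, breakpoints, ages, correlation."""

import math

import numpy as np
import pandas as pd
import pytest

from rediplo.homeopair import pair_contigs, seed_and_chain
from rediplo.indeltx import (
    IndelEvent,
    breakpoint_composition,
    classify_te_overlap,
    extract_indels,
    identity_te_correlation,
    landscape_mode,
    te_age_landscape,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _events_from_truth(sim):
    out = []
    for t in sim.truth.te_insertions + sim.truth.non_te_indels:
        out.append(IndelEvent(pairing="truth", carrier="a",
                              contig=t["contig"], start=t["start"],
                              end=t["start"] + t["length"],
                              length=t["length"]))
    return out


def test_zero_divergence_duplicates_no_events(rng):
    seq = _random_seq(rng, 30_000)
    pairings = pair_contigs(seed_and_chain({"A": seq, "B": seq}),
                            {"A": len(seq), "B": len(seq)})
    events, unresolved = extract_indels(pairings)
    assert events == [] and unresolved == []


def test_single_forced_insertion_recovered(rng):
    seq = _random_seq(rng, 40_000)
    ins = _random_seq(rng, 500)
    p = 17_530
    other = seq[:p] + ins + seq[p:]
    seqs = {"A": seq, "B": other}
    pairings = pair_contigs(seed_and_chain(seqs),
                            {c: len(s) for c, s in seqs.items()})
    events, _ = extract_indels(pairings, sequences=seqs)
    assert len(events) == 1
    ev = events[0]
    assert ev.carrier == "b"
    assert abs(ev.length - 500) <= 10
    assert abs(ev.start - p) <= 10


def test_truth_insertions_recovered_with_tight_breakpoints(small_sim,
                                                          small_pairings):
    events, _ = extract_indels(small_pairings, sequences=small_sim.sequences)
    by_contig = {}
    for e in events:
        by_contig.setdefault(e.contig, []).append(e)
    truth = small_sim.truth.te_insertions + small_sim.truth.non_te_indels
    hit = sum(
        any(abs(e.start - t["start"]) <= 20
            for e in by_contig.get(t["contig"], []))
        for t in truth
    )
    assert hit / len(truth) >= 0.9


def test_events_map_to_gaps_and_lengths_bounded(small_sim, small_pairings):
    events, _ = extract_indels(small_pairings, sequences=small_sim.sequences)
    gap_diff = sum(
        abs((ga[1] - ga[0]) - (gb[1] - gb[0]))
        for p in small_pairings for ga, gb in p.gaps
    )
    assert sum(e.length for e in events) <= gap_diff
    n_gaps = sum(len(p.gaps) for p in small_pairings)
    assert len(events) <= n_gaps


def test_classify_no_te_records_zero_percent(small_sim, small_pairings):
    events, _ = extract_indels(small_pairings, sequences=small_sim.sequences)
    empty = small_sim.te_table.iloc[0:0]
    _, pct = classify_te_overlap(events, empty)
    assert pct == 0.0


def test_classify_all_inside_te_is_hundred_percent():
    events = [IndelEvent("p", "a", "c1", 100, 600, 500)]
    te = pd.DataFrame([("c1", 0, 1000, "fam", 0, "+", "DNA", 1.0)],
                      columns=["contig", "start", "end", "family", "score",
                               "strand", "te_class", "pct_divergence"])
    classified, pct = classify_te_overlap(events, te)
    assert pct == 100.0
    assert classified[0].te_family == "fam"
    assert classified[0].te_overlap_fraction == 1.0


def test_classify_unknown_contig_rejected():
    events = [IndelEvent("p", "a", "c1", 100, 600, 500)]
    te = pd.DataFrame([("ghost", 0, 1000, "fam", 0, "+", "DNA", 1.0)],
                      columns=["contig", "start", "end", "family", "score",
                               "strand", "te_class", "pct_divergence"])
    with pytest.raises(ValueError, match="ghost"):
        classify_te_overlap(events, te, known_contigs={"c1"})


def test_classify_monotone_in_min_overlap(small_sim, small_pairings):
    events, _ = extract_indels(small_pairings, sequences=small_sim.sequences)
    pcts = []
    for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
        _, pct = classify_te_overlap(events, small_sim.te_table,
                                     min_overlap=thr)
        pcts.append(pct)
    assert all(a >= b for a, b in zip(pcts, pcts[1:]))


def test_breakpoint_ta_fraction_matches_preference(small_sim):
    """At generator-truth coordinates the TA breakpoint fraction must sit in
    the binomial interval of the configured TA preference (0.8)."""
    events = _events_from_truth(small_sim)
    comp = breakpoint_composition(events, small_sim.sequences)
    ta = comp.loc[comp["dinucleotide"] == "TA"].iloc[0]
    n = comp.attrs["n_events"]
    se = math.sqrt(0.8 * 0.2 / n)
    assert abs(ta["obs_freq"] - 0.8) <= 4 * se
    assert ta["enrichment"] > 3
    assert ta["p_binomial"] < 1e-6


def test_breakpoint_detected_events_still_ta_enriched(small_sim,
                                                      small_pairings):
    events, _ = extract_indels(small_pairings, sequences=small_sim.sequences)
    comp = breakpoint_composition(events, small_sim.sequences)
    ta = comp.loc[comp["dinucleotide"] == "TA"].iloc[0]
    assert ta["enrichment"] > 2
    assert ta["p_binomial"] < 1e-4


def test_breakpoint_contig_edges_skipped():
    seqs = {"c1": "ACGTTA" * 100}
    events = [IndelEvent("p", "a", "c1", 0, 50, 50),
              IndelEvent("p", "a", "c1", 500, 600, 100)]
    comp = breakpoint_composition(events, seqs)
    assert comp.attrs["skipped"] == 2  # one at edge, one ends at len(seq)


def test_te_age_zero_divergence_and_linearity():
    te = pd.DataFrame([("c1", 0, 100, "f", 0, "+", "DNA", 0.0),
                       ("c1", 200, 300, "f", 0, "+", "DNA", 2.0)],
                      columns=["contig", "start", "end", "family", "score",
                               "strand", "te_class", "pct_divergence"])
    land = te_age_landscape(te, rate=3.51e-9)
    ages = te["pct_divergence"] / 100 / 3.51e-9 / 1e6
    assert ages.iloc[0] == 0.0
    land2 = te_age_landscape(te, rate=2 * 3.51e-9)
    # doubling the rate halves every age bin
    a1 = sorted(land.loc[land.family == "f", "age_bin"])
    a2 = sorted(land2.loc[land2.family == "f", "age_bin"])
    assert a2[-1] <= a1[-1] / 2 + 0.25


def test_burst_age_recovered_from_landscape(small_sim):
    land = te_age_landscape(small_sim.te_table, small_sim.config.syn_rate)
    mode = landscape_mode(land)
    assert abs(mode - 3.0) <= 0.5


def test_identity_te_correlation_negative(small_sim, small_pairings):
    r, p, table = identity_te_correlation(
        small_pairings, small_sim.te_table, small_sim.contig_lengths,
        window=20_000)
    assert len(table) >= 30
    assert r < 0
    assert p < 0.05


def test_identity_te_correlation_zero_variance_flagged(small_pairings,
                                                       small_sim):
    te = small_sim.te_table.iloc[0:0]
    r, p, table = identity_te_correlation(
        small_pairings, te, small_sim.contig_lengths, window=20_000)
    assert math.isnan(r) and math.isnan(p)
    assert table.attrs["degenerate"]


def test_identity_te_correlation_too_few_windows(small_sim, small_pairings):
    with pytest.raises(ValueError, match="smaller window"):
        identity_te_correlation(small_pairings, small_sim.te_table,
                                small_sim.contig_lengths, window=500_000)
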