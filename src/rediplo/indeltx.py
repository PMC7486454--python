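"""Indel differences between homeologous regions and their transposon story.

Insertions/deletions are read off the inter-HSP gaps of each homeolog
chain: a gap whose spans on the two contigs differ by ≥ min_indel_len is an
indel event carried by the longer side.  Events are intersected with the TE
annotation, breakpoint dinucleotides are profiled for TA target-site
enrichment, per-family divergence-from-consensus landscapes date the
insertion bursts, and window-level HSP identity is correlated with local TE
density.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .homeopair import HomeologPairing


@dataclasses.dataclass
class IndelEvent:
    """An insertion on ``carrier`` relative to its homeolog.

    ``start``/``end`` are 0-based half-open on the carrier contig; length is
    the span difference between the two sides of the chain gap."""

    pairing: str
    carrier: str          # 'a' or 'b'
    contig: str
    start: int
    end: int
    length: int
    te_overlap_fraction: float = 0.0
    te_family: str | None = None
    breakpoint_dinucleotide: str = ""


_COMP = str.maketrans("ACGTN", "TGCAN")


def _xdrop_prefix(long_seq: str, short_seq: str, match: int = 1,
                  mismatch: int = -3, xdrop: int = 12) -> int:
    """Length of the leftmost maximal-scoring common prefix.

    Greedy ungapped extension tolerant of scattered substitutions: the
    score climbs through diverged-but-homologous flank sequence and
    collapses once the inserted (random) sequence starts, so the argmax
    marks the insertion junction."""
    best = score = 0
    best_len = 0
    for i in range(min(len(long_seq), len(short_seq))):
        score += match if long_seq[i] == short_seq[i] else mismatch
        if score > best:
            best, best_len = score, i + 1
        elif best - score > xdrop:
            break
    return best_len


def extract_indels(pairings: Sequence[HomeologPairing],
                   min_indel_len: int = 50,
                   max_indel_len: int = 100_000,
                   sequences: dict[str, str] | None = None,
                   ) -> tuple[list[IndelEvent], list[IndelEvent]]:
    """Read indel events off chain gaps.

    Returns (events, unresolved): gaps with span difference ≥ min_indel_len
    become events on the longer-span carrier (the interval is the gap on the
    carrier trimmed by the shared shorter span, so length = span
    difference); gaps where either span exceeds max_indel_len are reported
    separately as unresolved.

    When ``sequences`` is given, event boundaries are refined: the two gap
    sequences are extended into each other from both ends with an x-drop
    ungapped scan, so the reported interval starts at the insertion
    junction itself rather than at the last exact seed match.
    """
    events: list[IndelEvent] = []
    unresolved: list[IndelEvent] = []
    for p in pairings:
        name = f"{p.contig_a}|{p.contig_b}"
        minus = p.strand == "-"
        for (a_start, a_end), (b_start, b_end) in p.gaps:
            span_a = a_end - a_start
            span_b = b_end - b_start
            diff = abs(span_a - span_b)
            if diff < min_indel_len:
                continue
            if span_a >= span_b:
                carrier, contig = "a", p.contig_a
                start, end = a_start, a_end
                other_contig, o_start, o_end = p.contig_b, b_start, b_end
            else:
                carrier, contig = "b", p.contig_b
                start, end = b_start, b_end
                other_contig, o_start, o_end = p.contig_a, a_start, a_end
            short_span = min(span_a, span_b)
            if sequences is not None and short_span > 0:
                gap_long = sequences[contig][start:end]
                gap_short = sequences[other_contig][o_start:o_end]
                if minus:
                    # gap sequences run in opposite orientations
                    gap_short = gap_short.translate(_COMP)[::-1]
                left = _xdrop_prefix(gap_long, gap_short)
                right = _xdrop_prefix(gap_long[::-1], gap_short[::-1])
                if left + right > short_span:
                    right = short_span - left
                start, end = start + left, end - right
            else:
                end = end - short_span
            if end - start < min_indel_len:
                # refinement over-trimmed; fall back to the raw trim
                start = a_start if carrier == "a" else b_start
                end = start + diff
            ev = IndelEvent(pairing=name, carrier=carrier, contig=contig,
                            start=start, end=end, length=diff)
            if max(span_a, span_b) > max_indel_len:
                unresolved.append(ev)
            else:
                events.append(ev)
    return events, unresolved


def _te_trees(te_records: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in te_records.itertuples(index=False):
        trees.setdefault(row.contig, IntervalTree()).addi(
            int(row.start), int(row.end), row.family)
    return trees


def classify_te_overlap(events: Sequence[IndelEvent],
                        te_records: pd.DataFrame,
                        min_overlap: float = 0.5,
                        known_contigs: set[str] | None = None,
                        ) -> tuple[list[IndelEvent], float]:
    """Mark events covered ≥ min_overlap by TE annotation.

    Returns the events (with te_overlap_fraction and dominant te_family
    filled in) and the TE-classified percentage among all events."""
    if known_contigs is not None:
        bad = sorted(set(te_records["contig"]) - known_contigs)
        if bad:
            raise ValueError(f"TE records reference unknown contigs: {bad}")
    trees = _te_trees(te_records)
    n_te = 0
    for ev in events:
        tree = trees.get(ev.contig)
        if tree is None:
            ev.te_overlap_fraction = 0.0
            continue
        hits = tree.overlap(ev.start, ev.end)
        if not hits:
            ev.te_overlap_fraction = 0.0
            continue
        # merged coverage and per-family attribution
        segs = sorted((max(ev.start, iv.begin), min(ev.end, iv.end), iv.data)
                      for iv in hits)
        fam_cov: dict[str, int] = {}
        covered = 0
        cur_end = ev.start
        for s, e, fam in segs:
            fam_cov[fam] = fam_cov.get(fam, 0) + (e - s)
            s = max(s, cur_end)
            if e > s:
                covered += e - s
                cur_end = e
        ev.te_overlap_fraction = covered / (ev.end - ev.start)
        if ev.te_overlap_fraction >= min_overlap:
            ev.te_family = max(sorted(fam_cov), key=lambda f: fam_cov[f])
            n_te += 1
        else:
            ev.te_family = None
    pct = 100.0 * n_te / len(events) if events else 0.0
    return list(events), pct


def breakpoint_composition(events: Sequence[IndelEvent],
                           sequences: dict[str, str],
                           ) -> pd.DataFrame:
    """Dinucleotide spelled by the two carrier bases flanking each inserted
    interval, versus the genome-wide dinucleotide background.

    Returns a table with observed counts/frequencies, expected background
    frequency, enrichment (obs/exp) and a binomial p-value per dinucleotide.
    Events touching a contig edge are skipped (counted in the 'skipped'
    attribute of the frame)."""
    counts: dict[str, int] = {}
    skipped = 0
    for ev in events:
        seq = sequences[ev.contig]
        if ev.start < 1 or ev.end >= len(seq):
            skipped += 1
            continue
        dinuc = (seq[ev.start - 1] + seq[ev.end]).upper()
        if set(dinuc) - set("ACGT"):
            skipped += 1
            continue
        counts[dinuc] = counts.get(dinuc, 0) + 1
        if ev.breakpoint_dinucleotide == "":
            ev.breakpoint_dinucleotide = dinuc
    total = sum(counts.values())
    # genome background over all adjacent base pairs
    bg: dict[str, int] = {}
    for seq in sequences.values():
        s = seq.upper()
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        enc = np.full(arr.shape, 255, np.uint8)
        for b, v in code.items():
            enc[arr == ord(b)] = v
        ok = (enc[:-1] <= 3) & (enc[1:] <= 3)
        pairs = enc[:-1][ok].astype(int) * 4 + enc[1:][ok]
        binc = np.bincount(pairs, minlength=16)
        bases = "ACGT"
        for idx, n in enumerate(binc):
            d = bases[idx // 4] + bases[idx % 4]
            bg[d] = bg.get(d, 0) + int(n)
    bg_total = sum(bg.values())
    rows = []
    for d in sorted(set(counts) | set(bg)):
        obs = counts.get(d, 0)
        exp_freq = bg.get(d, 0) / bg_total if bg_total else 0.0
        obs_freq = obs / total if total else 0.0
        enr = obs_freq / exp_freq if exp_freq > 0 else math.nan
        if total and 0 < exp_freq < 1:
            p = stats.binomtest(obs, total, exp_freq).pvalue
        else:
            p = math.nan
        rows.append((d, obs, obs_freq, exp_freq, enr, p))
    df = pd.DataFrame(rows, columns=["dinucleotide", "observed", "obs_freq",
                                     "exp_freq", "enrichment", "p_binomial"])
    df.attrs["skipped"] = skipped
    df.attrs["n_events"] = total
    return df


def te_age_landscape(te_records: pd.DataFrame, rate: float,
                     bin_mya: float = 0.25) -> pd.DataFrame:
    """Insertion-age histogram from divergence-to-consensus.

    Age (Mya) = (pct_divergence / 100) / rate / 1e6 under a single-lineage
    clock: the consensus stands for the ancestral active element, and each
    copy alone has accumulated the divergence (not 2r, a convention to note
    when comparing with pairwise dates).  Binned at ``bin_mya`` per family
    and in aggregate (family = 'ALL')."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    te = te_records.copy()
    te["age_mya"] = te["pct_divergence"] / 100.0 / rate / 1e6
    te["age_bin"] = (te["age_mya"] / bin_mya).astype(int) * bin_mya
    per_fam = (te.groupby(["family", "age_bin"]).size()
               .rename("copy_count").reset_index())
    agg = te.groupby("age_bin").size().rename("copy_count").reset_index()
    agg.insert(0, "family", "ALL")
    return pd.concat([per_fam, agg], ignore_index=True)


def landscape_mode(landscape: pd.DataFrame, family: str = "ALL") -> float:
    """Age-bin midpoint with the most copies for one family."""
    sub = landscape[landscape["family"] == family]
    if sub.empty:
        raise ValueError(f"no landscape rows for family {family}")
    row = sub.loc[sub["copy_count"].idxmax()]
    bins = sorted(sub["age_bin"].unique())
    width = min(np.diff(bins)) if len(bins) > 1 else 0.25
    return float(row["age_bin"]) + width / 2.0


def identity_te_correlation(pairings: Sequence[HomeologPairing],
                            te_records: pd.DataFrame,
                            contig_lengths: dict[str, int],
                            window: int = 100_000,
                            min_windows: int = 30,
                            ) -> tuple[float, float, pd.DataFrame]:
    """Correlate window-level HSP identity with TE coverage.

    Non-overlapping windows are laid over every contig participating in a
    pairing; each window gets the length-weighted mean identity of the HSP
    portions inside it and the fraction of the window covered by TE
    records.  Windows without HSP coverage are dropped.  Returns Pearson r,
    its two-sided p, and the window table (Spearman columns included in
    ``attrs`` as a robustness check).
    """
    te_trees = _te_trees(te_records)
    rows = []
    for p in pairings:
        for side in ("a", "b"):
            contig = p.contig_a if side == "a" else p.contig_b
            L = contig_lengths[contig]
            n_win = L // window
            if n_win == 0:
                continue
            id_w = np.zeros(n_win)
            len_w = np.zeros(n_win)
            for h in p.chain:
                s = h.start_a if side == "a" else h.start_b
                e = h.end_a if side == "a" else h.end_b
                w0, w1 = s // window, min((e - 1) // window, n_win - 1)
                for w in range(w0, w1 + 1):
                    lo, hi = max(s, w * window), min(e, (w + 1) * window)
                    if hi > lo:
                        id_w[w] += h.identity * (hi - lo)
                        len_w[w] += hi - lo
            te_cov = np.zeros(n_win)
            tree = te_trees.get(contig)
            if tree is not None:
                for iv in tree:
                    w0 = iv.begin // window
                    w1 = min((iv.end - 1) // window, n_win - 1)
                    for w in range(w0, w1 + 1):
                        lo = max(iv.begin, w * window)
                        hi = min(iv.end, (w + 1) * window)
                        te_cov[w] += max(hi - lo, 0)
            for w in range(n_win):
                if len_w[w] > 0:
                    rows.append((contig, w * window, (w + 1) * window,
                                 id_w[w] / len_w[w],
                                 min(te_cov[w] / window, 1.0)))
    table = pd.DataFrame(rows, columns=["contig", "start", "end",
                                        "mean_hsp_identity", "te_density"])
    if len(table) < min_windows:
        raise ValueError(
            f"only {len(table)} windows with HSP coverage (<{min_windows}); "
            "use a smaller window size"
        )
    if table["mean_hsp_identity"].nunique() == 1 or table["te_density"].nunique() == 1:
        table.attrs["degenerate"] = True
        return math.nan, math.nan, table
    r, p_val = stats.pearsonr(table["mean_hsp_identity"], table["te_density"])
    rho, p_rho = stats.spearmanr(table["mean_hsp_identity"], table["te_density"])
    table.attrs["spearman_rho"] = float(rho)
    table.attrs["spearman_p"] = float(p_rho)
    table.attrs["degenerate"] = False
    return float(r), float(p_val), table


def events_to_bed(events: Sequence[IndelEvent]) -> pd.DataFrame:
    """Indel events as a BED-like frame (name = TE family or 'non-TE')."""
    return pd.DataFrame(
        [(e.contig, e.start, e.end, e.te_family or "non-TE", e.length,
          e.carrier, round(e.te_overlap_fraction, 4), e.breakpoint_dinucleotide)
         for e in events],
        columns=["contig", "start", "end", "name", "length", "carrier",
                 "te_overlap_fraction", "breakpoint_dinucleotide"],
    )
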