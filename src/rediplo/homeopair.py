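"""Identify WGD-derived duplicated contig pairs and call ohnolog genes.

Strategy: exact k-mer seeds between distinct contigs are grouped by
diagonal into ungapped high-scoring segment pairs (HSPs, identity computed
exactly over all aligned columns), the HSPs are chained by sparse dynamic
programming into a colinear chain per contig pair (gap ≤ max_gap), contigs
are paired reciprocal-best by total chained aligned length, and genes are
projected through the chain to find their duplicate partner (reciprocal
best by CDS identity).

Repetitive k-mers (more than ``max_occ`` hits on a target contig) are not
seeded, so transposon bodies do not generate spurious homeology — they
surface instead as inter-HSP gaps, which is exactly where the downstream
indel caller looks.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import GeneModel

logger = logging.getLogger(__name__)

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclasses.dataclass(frozen=True)
class HSP:
    """An ungapped aligned segment between two contigs.

    Coordinates are 0-based half-open on both contigs; ``start_b``/``end_b``
    are always on the forward strand of contig_b.  For strand '-' the
    segment pairs position ``start_a + i`` with ``end_b - 1 - i``.
    """

    contig_a: str
    start_a: int
    end_a: int
    contig_b: str
    start_b: int
    end_b: int
    strand: str
    identity: float
    aligned_length: int
    matches: int

    def __post_init__(self):
        if self.end_a <= self.start_a or self.end_b <= self.start_b:
            raise ValueError("HSP with empty span")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity outside [0, 100]")
        if self.matches > self.aligned_length:
            raise ValueError("matches exceed aligned length")


@dataclasses.dataclass
class HomeologPairing:
    """A reciprocal-best duplicated contig pair with its colinear chain."""

    contig_a: str
    contig_b: str
    chain: list[HSP]
    gaps: list[tuple[tuple[int, int], tuple[int, int]]]
    coverage_a: float
    coverage_b: float

    @property
    def aligned_length(self) -> int:
        return sum(h.aligned_length for h in self.chain)

    @property
    def strand(self) -> str:
        return self.chain[0].strand if self.chain else "+"

    def project(self, pos: int) -> int:
        """Map a position on contig_a to contig_b via the containing HSP,
        extrapolating from the nearest HSP when the position falls in a gap."""
        best = None
        best_dist = None
        for h in self.chain:
            if h.start_a <= pos < h.end_a:
                best, best_dist = h, 0
                break
            d = min(abs(pos - h.start_a), abs(pos - h.end_a))
            if best_dist is None or d < best_dist:
                best, best_dist = h, d
        if best is None:
            raise ValueError("empty chain")
        off = pos - best.start_a
        if best.strand == "+":
            return best.start_b + off
        return best.end_b - 1 - off


@dataclasses.dataclass(frozen=True)
class OhnologPair:
    gene_a: str
    gene_b: str
    contig_a: str
    contig_b: str
    anchor_identity: float


# ------------------------------------------------------------------ seeding

def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers plus a validity mask (no ambiguous base)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    enc = np.full(arr.shape, 255, dtype=np.uint8)
    for b, v in _ENC.items():
        enc[arr == ord(b)] = v
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    e64 = enc.astype(np.int64)
    for j in range(k):
        codes = codes * 4 + np.where(enc[j:j + n] > 3, 0, e64[j:j + n])
        bad |= enc[j:j + n] > 3
    return codes, ~bad


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.upper().translate(comp)[::-1]


def _match_positions(codes_a: np.ndarray, valid_a: np.ndarray,
                     codes_b: np.ndarray, valid_b: np.ndarray,
                     max_occ: int) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) with codes_a[i] == codes_b[j], skipping k-mers occurring
    more than max_occ times on the target."""
    pos_b = np.flatnonzero(valid_b)
    cb = codes_b[pos_b]
    order = np.argsort(cb, kind="stable")
    sb = cb[order]
    pb = pos_b[order]
    pos_a = np.flatnonzero(valid_a)
    ca = codes_a[pos_a]
    left = np.searchsorted(sb, ca, side="left")
    right = np.searchsorted(sb, ca, side="right")
    cnt = right - left
    keep = (cnt > 0) & (cnt <= max_occ)
    pos_a, left, cnt = pos_a[keep], left[keep], cnt[keep]
    single = cnt == 1
    i_parts = [np.repeat(pos_a[single], 1)]
    j_parts = [pb[left[single]]]
    multi_idx = np.flatnonzero(~single)
    for m in multi_idx:
        c = cnt[m]
        i_parts.append(np.full(c, pos_a[m]))
        j_parts.append(pb[left[m]:left[m] + c])
    if not i_parts:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(i_parts), np.concatenate(j_parts)


def _segments_from_anchors(i: np.ndarray, j: np.ndarray, k: int,
                           join_gap: int) -> list[tuple[int, int, int]]:
    """Merge same-diagonal anchors into ungapped segments.

    Returns (start_a, end_a, diag) with diag = i − j; anchors on one
    diagonal separated by ≤ join_gap unanchored bases are merged (isolated
    substitutions leave a k-sized anchor hole, well under join_gap)."""
    if i.size == 0:
        return []
    diag = i - j
    order = np.lexsort((i, diag))
    i, diag = i[order], diag[order]
    breaks = np.flatnonzero(
        (np.diff(diag) != 0) | (np.diff(i) > join_gap)
    )
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [i.size - 1]])
    return [(int(i[s]), int(i[e]) + k, int(diag[s]))
            for s, e in zip(starts, ends)]


def _enc_array(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    return arr


def _chain_segments(segs: list[tuple[int, int, int]], enc_a: np.ndarray,
                    enc_b: np.ndarray, min_hsp_len: int, max_gap: int,
                    k: int) -> list[tuple[int, int, int, int]]:
    """Sparse-DP colinear chain over ungapped segments.

    Segments are (start_a, end_a, diag); returns chained, trimmed,
    non-overlapping (start_a, end_a, start_b, matches) sorted by start_a.
    Score maximized is total exact matches."""
    if not segs:
        return []
    segs = sorted(segs, key=lambda s: (s[0], s[1]))
    n = len(segs)
    matches = np.empty(n, dtype=np.int64)
    for idx, (sa, ea, d) in enumerate(segs):
        matches[idx] = int(np.count_nonzero(
            enc_a[sa:ea] == enc_b[sa - d:ea - d]))
    score = matches.astype(float).copy()
    parent = np.full(n, -1, dtype=np.int64)
    for idx in range(n):
        sa, ea, d = segs[idx]
        sb = sa - d
        for p in range(idx):
            _pa, pea, pd_ = segs[p]
            peb = pea - pd_
            gap_a = sa - pea
            gap_b = sb - peb
            # colinear, up to k bp of seed overlap, gaps bounded
            if gap_a < -k or gap_b < -k or gap_a > max_gap or gap_b > max_gap:
                continue
            cand = score[p] + matches[idx]
            if cand > score[idx]:
                score[idx] = cand
                parent[idx] = p
    best = int(np.argmax(score))
    chain_idx = []
    while best >= 0:
        chain_idx.append(best)
        best = int(parent[best])
    chain_idx.reverse()
    # trim overlaps and recompute matches exactly
    out = []
    prev_ea = prev_eb = -1
    for idx in chain_idx:
        sa, ea, d = segs[idx]
        sb = sa - d
        trim = max(prev_ea - sa, prev_eb - sb, 0)
        sa += trim
        sb += trim
        if ea - sa < min_hsp_len:
            continue
        m = int(np.count_nonzero(enc_a[sa:ea] == enc_b[sb:ea - d]))
        out.append((sa, ea, sb, m))
        prev_ea, prev_eb = ea, ea - d
    return out


def seed_and_chain(sequences: dict[str, str], k: int = 15,
                   min_hsp_len: int = 100, max_gap: int = 20_000,
                   max_occ: int = 8, join_gap: int = 80) -> list[HSP]:
    """All-vs-all homeology search over a contig set.

    For every unordered pair of distinct contigs, both orientations are
    seeded and the better-scoring orientation's colinear chain is returned
    as a list of HSPs (each pair stored once with the lexicographically
    smaller contig as contig_a).
    """
    if k < 11:
        raise ValueError("k must be ≥ 11")
    names = sorted(sequences)
    usable = []
    for name in names:
        if len(sequences[name]) < k:
            warnings.warn(f"contig {name} shorter than k={k}: skipped")
            continue
        usable.append(name)
    codes = {n: _kmer_codes(sequences[n], k) for n in usable}
    rc_seqs = {n: _revcomp(sequences[n]) for n in usable}
    rc_codes = {n: _kmer_codes(rc_seqs[n], k) for n in usable}
    enc = {n: _enc_array(sequences[n]) for n in usable}
    rc_enc = {n: _enc_array(rc_seqs[n]) for n in usable}

    hsps: list[HSP] = []
    for ai in range(len(usable)):
        for bi in range(ai + 1, len(usable)):
            a, b = usable[ai], usable[bi]
            len_b = len(sequences[b])
            best_chain = None
            best_strand = "+"
            best_score = -1
            for strand in ("+", "-"):
                cb, vb = codes[b] if strand == "+" else rc_codes[b]
                eb = enc[b] if strand == "+" else rc_enc[b]
                i, j = _match_positions(*codes[a], cb, vb, max_occ)
                segs = _segments_from_anchors(i, j, k, join_gap)
                segs = [s for s in segs if s[1] - s[0] >= min_hsp_len]
                chain = _chain_segments(segs, enc[a], eb, min_hsp_len,
                                        max_gap, k)
                total = sum(m for *_c, m in chain)
                if total > best_score:
                    best_score, best_chain, best_strand = total, chain, strand
            if not best_chain:
                continue
            for sa, ea, sb, m in best_chain:
                length = ea - sa
                if best_strand == "+":
                    b_start, b_end = sb, sb + length
                else:
                    b_start, b_end = len_b - (sb + length), len_b - sb
                hsps.append(HSP(
                    contig_a=a, start_a=sa, end_a=ea,
                    contig_b=b, start_b=b_start, end_b=b_end,
                    strand=best_strand,
                    identity=100.0 * m / length,
                    aligned_length=length, matches=m,
                ))
    return hsps


# ------------------------------------------------------------------ pairing

def pair_contigs(hsps: Sequence[HSP], contig_lengths: dict[str, int],
                 min_coverage: float = 0.5) -> list[HomeologPairing]:
    """Reciprocal-best pairing of contigs by total chained aligned length.

    A pairing is kept when each contig's best partner is the other and the
    chain covers ≥ min_coverage of the shorter contig.  Ties are broken
    lexicographically (and logged).  Unpaired contigs are simply absent."""
    totals: dict[tuple[str, str], int] = {}
    by_pair: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        key = (h.contig_a, h.contig_b)
        totals[key] = totals.get(key, 0) + h.aligned_length
        by_pair.setdefault(key, []).append(h)

    best: dict[str, tuple[int, str]] = {}
    for (a, b), tot in sorted(totals.items()):
        for me, other in ((a, b), (b, a)):
            cur = best.get(me)
            if cur is None or tot > cur[0]:
                best[me] = (tot, other)
            elif tot == cur[0] and other < cur[1]:
                logger.info("tie for %s between %s and %s: keeping %s",
                            me, cur[1], other, other)
                best[me] = (tot, other)

    pairings = []
    for (a, b), chain in sorted(by_pair.items()):
        if best.get(a, (0, None))[1] != b or best.get(b, (0, None))[1] != a:
            continue
        chain = sorted(chain, key=lambda h: h.start_a)
        aligned = sum(h.aligned_length for h in chain)
        shorter = min(contig_lengths[a], contig_lengths[b])
        cov_a = aligned / contig_lengths[a]
        cov_b = aligned / contig_lengths[b]
        if aligned / shorter < min_coverage:
            continue
        gaps = []
        for h1, h2 in zip(chain, chain[1:]):
            if h1.strand == "+":
                g_b = (h1.end_b, h2.start_b)
            else:
                g_b = (h2.end_b, h1.start_b)
            gaps.append(((h1.end_a, h2.start_a), g_b))
        pairings.append(HomeologPairing(
            contig_a=a, contig_b=b, chain=chain, gaps=gaps,
            coverage_a=cov_a, coverage_b=cov_b,
        ))
    return pairings


def assert_colinear(pairing: HomeologPairing) -> None:
    """Raise AssertionError unless the chain is monotone and non-overlapping
    on both contigs with a consistent strand."""
    chain = pairing.chain
    strands = {h.strand for h in chain}
    assert len(strands) <= 1, "mixed strands in chain"
    for h1, h2 in zip(chain, chain[1:]):
        assert h2.start_a >= h1.end_a, "overlap on contig_a"
        if h1.strand == "+":
            assert h2.start_b >= h1.end_b, "overlap on contig_b"
        else:
            assert h2.end_b <= h1.start_b, "overlap on contig_b (reverse)"


# ----------------------------------------------------------------- ohnologs

def _cds_identity(cds_a: str, cds_b: str) -> float:
    import edlib

    if not cds_a or not cds_b:
        return 0.0
    d = edlib.align(cds_a, cds_b, task="distance")["editDistance"]
    m = max(len(cds_a), len(cds_b))
    return 100.0 * (1.0 - d / m)


def call_ohnologs(pairings: Sequence[HomeologPairing],
                  genes: Sequence[GeneModel],
                  sequences: dict[str, str],
                  min_cds_identity: float = 80.0,
                  search_slack: int = 5000,
                  ) -> tuple[list[OhnologPair], list[str]]:
    """Call duplicate gene pairs anchored in paired contigs.

    Each gene on contig_a is projected through the chain; genes on contig_b
    within ``search_slack`` of the projected interval are candidates, scored
    by CDS identity (edit distance over the longer CDS).  Pairs are kept if
    reciprocal best and identity ≥ min_cds_identity.  Returns (pairs,
    singleton candidate gene ids); genes on unpaired contigs are excluded
    and counted in the log.
    """
    genes_by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig, []).append(g)
    paired_contigs = {p.contig_a for p in pairings} | {p.contig_b for p in pairings}
    n_excluded = sum(1 for g in genes if g.contig not in paired_contigs)
    if n_excluded:
        logger.info("%d genes on unpaired contigs excluded", n_excluded)

    pairs: list[OhnologPair] = []
    singletons: list[str] = []
    for pairing in pairings:
        ga = genes_by_contig.get(pairing.contig_a, [])
        gb = genes_by_contig.get(pairing.contig_b, [])
        if not ga or not gb:
            singletons.extend(g.gene_id for g in ga + gb)
            continue
        cds_cache = {g.gene_id: g.cds(sequences) for g in ga + gb}
        # score all candidate pairs within the projected window
        scores: dict[tuple[str, str], float] = {}
        for g in ga:
            try:
                p1 = pairing.project(g.start)
                p2 = pairing.project(max(g.start, g.end - 1))
            except ValueError:
                continue
            lo, hi = min(p1, p2) - search_slack, max(p1, p2) + search_slack
            for h in gb:
                if h.end < lo or h.start > hi:
                    continue
                scores[(g.gene_id, h.gene_id)] = _cds_identity(
                    cds_cache[g.gene_id], cds_cache[h.gene_id])
        best_a: dict[str, tuple[float, str]] = {}
        best_b: dict[str, tuple[float, str]] = {}
        for (a_id, b_id), ident in sorted(scores.items()):
            if a_id not in best_a or ident > best_a[a_id][0]:
                best_a[a_id] = (ident, b_id)
            if b_id not in best_b or ident > best_b[b_id][0]:
                best_b[b_id] = (ident, a_id)
        matched_a, matched_b = set(), set()
        for a_id, (ident, b_id) in sorted(best_a.items()):
            if ident < min_cds_identity:
                continue
            if best_b.get(b_id, (0, None))[1] != a_id:
                continue
            pairs.append(OhnologPair(
                gene_a=a_id, gene_b=b_id,
                contig_a=pairing.contig_a, contig_b=pairing.contig_b,
                anchor_identity=ident,
            ))
            matched_a.add(a_id)
            matched_b.add(b_id)
        singletons.extend(g.gene_id for g in ga if g.gene_id not in matched_a)
        singletons.extend(g.gene_id for g in gb if g.gene_id not in matched_b)
    return pairs, singletons


def duplicate_retention_percent(n_pairs: int, n_genes: int) -> float:
    """Percent of genes on paired contigs that sit in a duplicate pair:
    2 × pairs / genes × 100, rounded to two decimals."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return round(200.0 * n_pairs / n_genes, 2)


def fraction_percent(numerator: int, denominator: int) -> float:
    """numerator / denominator as a percentage rounded to two decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, 2)


# ---------------------------------------------------------------------- PAF

def write_paf(hsps: Iterable[HSP], contig_lengths: dict[str, int],
              path: str | Path) -> None:
    """Standard 12-column PAF (0-based half-open) plus an id:f identity tag."""
    with open(path, "w") as fh:
        for h in hsps:
            fh.write("\t".join(map(str, [
                h.contig_a, contig_lengths[h.contig_a], h.start_a, h.end_a,
                h.strand,
                h.contig_b, contig_lengths[h.contig_b], h.start_b, h.end_b,
                h.matches, h.aligned_length, 255,
                f"id:f:{h.identity:.6f}",
            ])) + "\n")


def read_paf(path: str | Path) -> tuple[list[HSP], dict[str, int]]:
    hsps = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            identity = None
            for tag in f[12:]:
                if tag.startswith("id:f:"):
                    identity = float(tag[5:])
            matches = int(f[9])
            alnlen = int(f[10])
            if identity is None:
                identity = 100.0 * matches / alnlen
            lengths[f[0]] = int(f[1])
            lengths[f[5]] = int(f[6])
            hsps.append(HSP(
                contig_a=f[0], start_a=int(f[2]), end_a=int(f[3]),
                contig_b=f[5], start_b=int(f[7]), end_b=int(f[8]),
                strand=f[4], identity=identity,
                aligned_length=alnlen, matches=matches,
            ))
    return hsps, lengths
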