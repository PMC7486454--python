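"""SNP-density enrichment around transposon insertion sites.

Tests whether population SNP density within ``flank_bp`` (default ±500 bp)
of transposon boundaries exceeds that of remote regions (≥ min_distance
from any TE) and randomly placed non-TE regions.  Flanks exclude TE bodies
and overlapping flanks are merged, so no SNP is counted twice.  Inference
is a Welch t test plus a label-permutation test on the mean difference, and
a distance-decay profile of SNP density in fixed bins from the nearest TE.
"""

from __future__ import annotations

import dataclasses
import warnings
import numpy as np
import pandas as pd
from scipy import stats

DISTANCE_BINS = ((0, 500), (500, 1000), (1000, 2000), (2000, 5000))


@dataclasses.dataclass
class FlankProfile:
    flank_bp: int
    density_flank: float
    density_remote: float
    density_random: float
    n_sites: int
    p_t_remote: float
    p_t_random: float
    p_perm_remote: float
    p_perm_random: float
    distance_profile: pd.DataFrame


def _snp_arrays(snps: pd.DataFrame) -> dict[str, np.ndarray]:
    return {c: np.sort(sub["pos"].to_numpy())
            for c, sub in snps.groupby("contig")}


def _merged_te(te_records: pd.DataFrame) -> dict[str, np.ndarray]:
    """Merged TE body intervals per contig as an (n, 2) array."""
    out = {}
    for c, sub in te_records.groupby("contig"):
        ivs = sub[["start", "end"]].sort_values("start").to_numpy()
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[c] = np.array(merged, dtype=int)
    return out


def _subtract(intervals: list[list[int]], blocks: np.ndarray) -> list[list[int]]:
    """Subtract sorted merged ``blocks`` from sorted merged ``intervals``."""
    out = []
    bi = 0
    for s, e in intervals:
        cur = s
        while bi < len(blocks) and blocks[bi][1] <= cur:
            bi += 1
        j = bi
        while j < len(blocks) and blocks[j][0] < e:
            bs, be = blocks[j]
            if bs > cur:
                out.append([cur, min(bs, e)])
            cur = max(cur, be)
            if cur >= e:
                break
            j += 1
        if cur < e:
            out.append([cur, e])
    return [iv for iv in out if iv[1] > iv[0]]


def _merge(intervals) -> list[list[int]]:
    merged: list[list[int]] = []
    for s, e in sorted(map(list, intervals)):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def _count_in(positions: np.ndarray, s: int, e: int) -> int:
    return int(np.searchsorted(positions, e) - np.searchsorted(positions, s))


def _check_contigs(snps: pd.DataFrame, te_records: pd.DataFrame,
                   contig_lengths: dict[str, int]) -> None:
    bad = sorted((set(snps["contig"]) | set(te_records["contig"]))
                 - set(contig_lengths))
    if bad:
        raise ValueError(f"contigs absent from the assembly: {bad}")


def flank_density(snps: pd.DataFrame, te_records: pd.DataFrame,
                  contig_lengths: dict[str, int],
                  flank_bp: int = 500) -> np.ndarray:
    """Per-region SNP densities (SNPs/kb) in merged non-TE flanks of TEs."""
    _check_contigs(snps, te_records, contig_lengths)
    pos = _snp_arrays(snps)
    bodies = _merged_te(te_records)
    densities = []
    for contig, sub in te_records.groupby("contig"):
        L = contig_lengths[contig]
        flanks = []
        for row in sub.itertuples(index=False):
            flanks.append([max(0, row.start - flank_bp), row.start])
            flanks.append([row.end, min(L, row.end + flank_bp)])
        flanks = _merge([f for f in flanks if f[1] > f[0]])
        flanks = _subtract(flanks, bodies.get(contig, np.empty((0, 2), int)))
        p = pos.get(contig, np.empty(0, int))
        for s, e in flanks:
            densities.append(_count_in(p, s, e) / (e - s) * 1000.0)
    return np.array(densities)


def control_densities(snps: pd.DataFrame, te_records: pd.DataFrame,
                      contig_lengths: dict[str, int],
                      n_controls: int, min_distance: int = 10_000,
                      region_len: int = 1000,
                      rng_seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Remote (≥ min_distance from any TE) and random (outside TE bodies)
    control regions, length-matched to a two-sided flank, with their SNP
    densities.  Placement is seeded and deterministic."""
    _check_contigs(snps, te_records, contig_lengths)
    rng = np.random.default_rng(rng_seed)
    pos = _snp_arrays(snps)
    bodies = _merged_te(te_records)

    def _placeable(exclusion_pad: int) -> list[tuple[str, int, int]]:
        spans = []
        for contig, L in sorted(contig_lengths.items()):
            b = bodies.get(contig, np.empty((0, 2), int))
            padded = _merge([[max(0, s - exclusion_pad), min(L, e + exclusion_pad)]
                             for s, e in b]) if len(b) else []
            free = _subtract([[0, L]], np.array(padded or np.empty((0, 2), int),
                                                dtype=int))
            for s, e in free:
                if e - s >= region_len:
                    spans.append((contig, s, e))
        return spans

    def _sample(spans, n) -> np.ndarray:
        total = sum(e - s - region_len + 1 for _c, s, e in spans)
        if total <= 0 or not spans:
            raise ValueError("no placeable control intervals")
        if n > total:
            raise ValueError(
                f"cannot place {n} controls; at most {total} start positions")
        weights = np.array([e - s - region_len + 1 for _c, s, e in spans],
                           dtype=float)
        out = []
        picks = rng.choice(len(spans), size=n, p=weights / weights.sum())
        for idx in picks:
            contig, s, e = spans[idx]
            start = int(rng.integers(s, e - region_len + 1))
            p = pos.get(contig, np.empty(0, int))
            out.append(_count_in(p, start, start + region_len)
                       / region_len * 1000.0)
        return np.array(out)

    remote = _sample(_placeable(min_distance), n_controls)
    random_ = _sample(_placeable(0), n_controls)
    return remote, random_


def _perm_p(x: np.ndarray, y: np.ndarray, n_perm: int,
            rng: np.random.Generator) -> float:
    """One-sided label-permutation p for mean(x) > mean(y)."""
    obs = x.mean() - y.mean()
    pooled = np.concatenate([x, y])
    n = len(x)
    idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)[:, :n]
    perm_x = pooled[idx]
    perm_means = perm_x.mean(axis=1)
    grand = pooled.sum()
    perm_y_means = (grand - perm_x.sum(axis=1)) / (pooled.size - n)
    diffs = perm_means - perm_y_means
    return float((1 + np.sum(diffs >= obs)) / (n_perm + 1))


def distance_profile(snps: pd.DataFrame, te_records: pd.DataFrame,
                     contig_lengths: dict[str, int],
                     bins=DISTANCE_BINS) -> pd.DataFrame:
    """SNP density by distance from the nearest TE edge (TE bodies and
    closer bins excluded), one row per bin."""
    pos = _snp_arrays(snps)
    bodies = _merged_te(te_records)
    rows = []
    for lo, hi in bins:
        n_snp = 0
        n_bp = 0
        for contig, L in sorted(contig_lengths.items()):
            b = bodies.get(contig, np.empty((0, 2), int))
            if len(b) == 0:
                continue
            outer = _merge([[max(0, s - hi), min(L, e + hi)] for s, e in b])
            inner = _merge([[max(0, s - lo), min(L, e + lo)] for s, e in b])
            ring = _subtract(outer, np.array(inner, dtype=int))
            p = pos.get(contig, np.empty(0, int))
            for s, e in ring:
                n_snp += _count_in(p, s, e)
                n_bp += e - s
        rows.append((lo, hi, n_snp, n_bp,
                     n_snp / n_bp * 1000.0 if n_bp else float("nan")))
    return pd.DataFrame(rows, columns=["dist_lo", "dist_hi", "n_snps",
                                       "n_bases", "density_per_kb"])


def enrichment_test(flank: np.ndarray, remote: np.ndarray,
                    random_: np.ndarray, snps: pd.DataFrame | None = None,
                    te_records: pd.DataFrame | None = None,
                    contig_lengths: dict[str, int] | None = None,
                    flank_bp: int = 500, n_perm: int = 1000,
                    rng_seed: int = 0) -> FlankProfile:
    """Welch t and permutation tests of flank vs control SNP densities."""
    if len(flank) < 30:
        raise ValueError(f"only {len(flank)} flank densities (<30)")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: permutation p-values coarse")
    rng = np.random.default_rng(rng_seed)
    p_t_remote = stats.ttest_ind(flank, remote, equal_var=False,
                                 alternative="greater").pvalue
    p_t_random = stats.ttest_ind(flank, random_, equal_var=False,
                                 alternative="greater").pvalue
    p_perm_remote = _perm_p(flank, remote, n_perm, rng)
    p_perm_random = _perm_p(flank, random_, n_perm, rng)
    if snps is not None and te_records is not None and contig_lengths:
        profile = distance_profile(snps, te_records, contig_lengths)
    else:
        profile = pd.DataFrame(columns=["dist_lo", "dist_hi", "n_snps",
                                        "n_bases", "density_per_kb"])
    return FlankProfile(
        flank_bp=flank_bp,
        density_flank=float(np.mean(flank)),
        density_remote=float(np.mean(remote)),
        density_random=float(np.mean(random_)),
        n_sites=len(flank),
        p_t_remote=float(p_t_remote),
        p_t_random=float(p_t_random),
        p_perm_remote=float(p_perm_remote),
        p_perm_random=float(p_perm_random),
        distance_profile=profile,
    )
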