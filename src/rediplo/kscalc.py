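"""NG86 Ka/Ks, 4DTv, Ks-distribution dating and selection scanning.

The estimator is Nei–Gojobori (1986) with Jukes–Cantor multiple-hit
correction: synonymous/nonsynonymous sites are counted per codon by
enumerating all nine single-base changes, differences between codons are
averaged with equal weights over all minimal mutational pathways that avoid
stop codons, and the proportions ps = Sd/S, pn = Nd/N are corrected with
k = -(3/4)·ln(1 - 4p/3).

4DTv is the fraction of fourfold-degenerate third-codon positions showing a
transversion; a site is eligible only when the first two codon positions are
identical across the pair and place the codon in a fourfold family.

The subgenome divergence date follows T = Ks_mode / (2r): both post-WGD
lineages accumulate substitutions at rate r, so the pairwise synonymous
distance grows at 2r per year.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy import stats

from ._codon import (
    PURINES,
    is_fourfold,
    is_stop,
    pathway_differences,
    site_counts,
)


@dataclasses.dataclass
class CodonAlignment:
    """Gap-free aligned codon columns of one CDS pair."""

    gene_a: str
    gene_b: str
    codons_a: list[str]
    codons_b: list[str]
    n_gapped_columns: int = 0

    @property
    def n_usable(self) -> int:
        return len(self.codons_a)


@dataclasses.dataclass
class KsEstimate:
    gene_a: str
    gene_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ks: float
    ka: float
    fourdtv: float
    n_4d_sites: int
    defined: bool

    @property
    def omega(self) -> float:
        """ka/ks; inf when ks == 0 and ka > 0, nan when both are 0."""
        if self.ks > 0:
            return self.ka / self.ks
        return math.inf if self.ka > 0 else math.nan


@dataclasses.dataclass(frozen=True)
class DivergenceDate:
    ks_mode: float
    rate: float
    time_years: float

    @property
    def time_mya(self) -> float:
        return round(self.time_years / 1e6, 2)


class InternalStopError(ValueError):
    """A CDS contains an in-frame stop codon before its last position."""


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _codons(cds: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and is_stop(codons[-1]):
        codons = codons[:-1]  # trailing stop never enters the alignment
    for i, c in enumerate(codons):
        if is_stop(c):
            raise InternalStopError(f"internal stop codon {c} at codon {i}")
    return codons


def align_codons(cds_a: str, cds_b: str,
                 gene_a: str = "a", gene_b: str = "b") -> CodonAlignment:
    """Codon-aware alignment: globally align the translated proteins
    (BLOSUM62, affine gaps) and back-map aligned residue columns to codons.
    Columns with a gap on either side are excluded from the usable set."""
    ca, cb = _codons(cds_a), _codons(cds_b)
    prot_a = str(Seq("".join(ca)).translate())
    prot_b = str(Seq("".join(cb)).translate())
    if prot_a == prot_b:
        aligned_pairs = list(zip(range(len(ca)), range(len(cb))))
        n_gapped = 0
    else:
        aln = _protein_aligner().align(prot_a, prot_b)[0]
        aligned_pairs = []
        n_gapped = 0
        blocks_a, blocks_b = aln.aligned
        prev_a = prev_b = 0
        for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
            n_gapped += (sa - prev_a) + (sb - prev_b)
            aligned_pairs.extend(zip(range(sa, ea), range(sb, eb)))
            prev_a, prev_b = ea, eb
        n_gapped += (len(prot_a) - prev_a) + (len(prot_b) - prev_b)
    return CodonAlignment(
        gene_a=gene_a,
        gene_b=gene_b,
        codons_a=[ca[i] for i, _ in aligned_pairs],
        codons_b=[cb[j] for _, j in aligned_pairs],
        n_gapped_columns=n_gapped,
    )


def jukes_cantor(p: float) -> float:
    """JC69 distance for a difference proportion p; requires p < 3/4."""
    if p >= 0.75:
        raise ValueError("proportion ≥ 3/4: JC correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(alignment: CodonAlignment) -> KsEstimate:
    """NG86 Ka/Ks with JC correction plus 4DTv for one aligned pair."""
    if alignment.n_usable == 0:
        raise ValueError("no usable codon columns")
    s_a = s_b = 0.0
    sd = nd = 0.0
    for codon_a, codon_b in zip(alignment.codons_a, alignment.codons_b):
        sa, _ = site_counts(codon_a)
        sb, _ = site_counts(codon_b)
        s_a += sa
        s_b += sb
        d_s, d_n = pathway_differences(codon_a, codon_b)
        sd += d_s
        nd += d_n
    total_sites = 3.0 * alignment.n_usable
    S = (s_a + s_b) / 2.0
    N = total_sites - S
    ps = sd / S if S > 0 else math.nan
    pn = nd / N if N > 0 else math.nan
    defined = S > 0 and ps < 0.75 and pn < 0.75
    ks = jukes_cantor(ps) if defined else math.nan
    ka = jukes_cantor(pn) if defined else math.nan
    fourdtv, n4d = compute_4dtv(alignment)
    return KsEstimate(
        gene_a=alignment.gene_a, gene_b=alignment.gene_b,
        S=S, N=N, Sd=sd, Nd=nd, ps=ps, pn=pn, ks=ks, ka=ka,
        fourdtv=fourdtv, n_4d_sites=n4d, defined=defined,
    )


def compute_4dtv(alignment: CodonAlignment) -> tuple[float, int]:
    """Transversion fraction at fourfold-degenerate third positions.

    Returns (fourdtv, n_4d_sites); fourdtv is nan when no site qualifies."""
    n4d = 0
    tv = 0
    for codon_a, codon_b in zip(alignment.codons_a, alignment.codons_b):
        if codon_a[:2] != codon_b[:2]:
            continue
        if not is_fourfold(codon_a):
            continue
        n4d += 1
        b1, b2 = codon_a[2], codon_b[2]
        if b1 != b2 and (b1 in PURINES) != (b2 in PURINES):
            tv += 1
    return (tv / n4d if n4d else math.nan), n4d


def ks_from_cds_pairs(pairs: Sequence[tuple[str, str, str, str]]) -> pd.DataFrame:
    """Estimate Ks/Ka/4DTv for (gene_a, gene_b, cds_a, cds_b) tuples.

    Pairs with internal stop codons are skipped with a diagnostic column.
    """
    rows = []
    for gene_a, gene_b, cds_a, cds_b in pairs:
        try:
            est = ng86(align_codons(cds_a, cds_b, gene_a, gene_b))
        except (InternalStopError, ValueError) as exc:
            rows.append({"gene_a": gene_a, "gene_b": gene_b,
                         "defined": False, "note": str(exc)})
            continue
        row = dataclasses.asdict(est)
        row["omega"] = est.omega
        row["note"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def ks_mode(ks_values: Sequence[float], bandwidth: str | float = "silverman",
            grid_points: int = 2048,
            min_bandwidth: float | None = None) -> float:
    """Mode of a Ks distribution by Gaussian KDE.

    Values are restricted to [0, 99th percentile] before density estimation
    so a long saturated tail cannot distort the peak.  Requires ≥30 values;
    with fewer, report the median instead of a density mode.

    ``min_bandwidth`` floors the kernel standard deviation (in Ks units).
    At low divergence each pair carries only a handful of synonymous
    differences, so the empirical Ks distribution is a discretized Poisson
    ratio; a kernel narrower than the per-pair counting error
    (≈ sqrt(Ks/S)) resolves those counting atoms rather than the
    underlying peak and biases the mode low.  Callers that know S should
    pass that error as the floor (see ``counting_se``).
    """
    vals = np.asarray([v for v in ks_values if np.isfinite(v)], dtype=float)
    if vals.size < 30:
        raise ValueError(
            f"only {vals.size} defined Ks values (<30); report the median "
            "rather than a KDE mode"
        )
    hi = np.quantile(vals, 0.99)
    vals = vals[(vals >= 0) & (vals <= hi)]
    if np.ptp(vals) == 0:
        return float(vals[0])
    kde = stats.gaussian_kde(vals, bw_method=bandwidth)
    if min_bandwidth is not None:
        sigma = vals.std(ddof=1)
        floor_factor = min_bandwidth / sigma if sigma > 0 else 0.0
        if kde.factor < floor_factor:
            kde = stats.gaussian_kde(vals, bw_method=floor_factor)
    grid = np.linspace(vals.min(), vals.max(), grid_points)
    return float(grid[np.argmax(kde(grid))])


def counting_se(estimates: pd.DataFrame) -> float:
    """Median per-pair counting standard error of Ks, sqrt(ks/S).

    Under the Poisson substitution model Sd ~ Poisson(ks·S), so one pair's
    Ks is measured with error ≈ sqrt(Sd)/S = sqrt(ks/S).  Used as the
    bandwidth floor when locating the Ks peak."""
    df = estimates[estimates["defined"].astype(bool)]
    if not len(df):
        return 0.0
    ks_med = max(float(df["ks"].median()), 0.0)
    s_med = float(df["S"].median())
    return math.sqrt(ks_med / s_med) if s_med > 0 else 0.0


def date_divergence(ks_mode_value: float, rate: float) -> DivergenceDate:
    """Date a WGD from the Ks peak: T = Ks / (2r) years."""
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    if ks_mode_value < 0:
        raise ValueError("Ks mode must be non-negative")
    years = ks_mode_value / (2.0 * rate)
    return DivergenceDate(ks_mode=ks_mode_value, rate=rate, time_years=years)


def kaks_selection_scan(estimates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag ohnolog pairs under putative positive selection.

    A pair is selected when ka/ks > 1 and a Fisher exact test on the 2×2
    table (Nd, N−Nd; Sd, S−Sd) — fractional counts rounded to the nearest
    integer — gives p < alpha.  A Benjamini–Hochberg FDR column is added.
    """
    from statsmodels.stats.multitest import multipletests

    df = estimates[estimates["defined"].astype(bool)].copy()
    pvals = []
    for row in df.itertuples(index=False):
        table = [
            [round(row.Nd), round(row.N - row.Nd)],
            [round(row.Sd), round(row.S - row.Sd)],
        ]
        pvals.append(stats.fisher_exact(table, alternative="greater")[1])
    df["p_fisher"] = pvals
    if len(df):
        df["fdr"] = multipletests(df["p_fisher"], method="fdr_bh")[1]
    else:
        df["fdr"] = []
    ratio = df["omega"].astype(float)
    df["selected"] = (ratio > 1.0) & (df["p_fisher"] < alpha)
    return df
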