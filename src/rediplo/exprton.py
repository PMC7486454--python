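"""Transposon-linked expression divergence of ohnolog pairs.

Ohnolog pairs are grouped by TE overlap — T (two genes overlap a TE), O
(one), N (none) — and compared on the off-gene ratio (fraction of genes
below an FPKM silencing threshold, per tissue) and on per-pair expression
divergence |log2((FPKM_a + 1)/(FPKM_b + 1))|.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .homeopair import OhnologPair
from .io import GeneModel


@dataclasses.dataclass(frozen=True)
class TONAssignment:
    gene_a: str
    gene_b: str
    group: str           # 'T', 'O' or 'N'
    te_overlap_a: bool
    te_overlap_b: bool


def assign_ton(ohnolog_pairs: Sequence[OhnologPair],
               gene_models: Sequence[GeneModel],
               te_records: pd.DataFrame,
               promoter_bp: int = 0) -> list[TONAssignment]:
    """Partition ohnolog pairs into T/O/N by TE overlap.

    A gene overlaps a TE when its gene-body interval — extended upstream by
    ``promoter_bp`` if given — intersects any TE record by ≥ 1 bp.  Pairs
    whose genes are missing from the annotation are excluded (counted in
    the returned list's length deficit)."""
    trees: dict[str, IntervalTree] = {}
    for row in te_records.itertuples(index=False):
        trees.setdefault(row.contig, IntervalTree()).addi(
            int(row.start), int(row.end))
    by_id = {g.gene_id: g for g in gene_models}

    def overlaps(gene_id: str) -> bool | None:
        g = by_id.get(gene_id)
        if g is None:
            return None
        s, e = g.start, g.end
        if promoter_bp:
            if g.strand == "+":
                s = max(0, s - promoter_bp)
            else:
                e = e + promoter_bp
        tree = trees.get(g.contig)
        return bool(tree and tree.overlap(s, e))

    out = []
    for p in ohnolog_pairs:
        fa, fb = overlaps(p.gene_a), overlaps(p.gene_b)
        if fa is None or fb is None:
            continue
        group = "T" if (fa and fb) else ("O" if (fa or fb) else "N")
        out.append(TONAssignment(p.gene_a, p.gene_b, group, fa, fb))
    return out


def off_gene_ratio(assignments: Sequence[TONAssignment],
                   expression: pd.DataFrame,
                   off_threshold: float = 1.0,
                   tissues: Sequence[str] | None = None) -> pd.DataFrame:
    """Off-gene ratio (silenced genes / genes) per group per tissue.

    A gene is silenced in a tissue when FPKM < off_threshold.  Pairwise
    two-proportion z-tests between groups are attached per tissue.
    """
    if tissues is not None:
        missing = [t for t in tissues if t not in expression.columns]
        if missing:
            raise ValueError(f"missing tissue columns: {missing}")
        expression = expression[list(tissues)]
    genes_in_group: dict[str, list[str]] = {"T": [], "O": [], "N": []}
    for a in assignments:
        for gid in (a.gene_a, a.gene_b):
            if gid in expression.index:
                genes_in_group[a.group].append(gid)
    rows = []
    for tissue in expression.columns:
        offs = {}
        ns = {}
        for grp, gids in genes_in_group.items():
            if not gids:
                offs[grp], ns[grp] = 0, 0
                continue
            vals = expression.loc[gids, tissue]
            offs[grp] = int((vals < off_threshold).sum())
            ns[grp] = len(gids)
        for grp in "TON":
            ratio = offs[grp] / ns[grp] if ns[grp] else float("nan")
            pvals = {}
            for other in "TON":
                if other == grp or not ns[grp] or not ns[other]:
                    continue
                from statsmodels.stats.proportion import proportions_ztest
                stat_p = proportions_ztest(
                    [offs[grp], offs[other]], [ns[grp], ns[other]])[1] \
                    if (offs[grp] + offs[other]) not in (0, ns[grp] + ns[other]) \
                    else 1.0
                pvals[f"p_vs_{other}"] = float(stat_p)
            rows.append({"group": grp, "tissue": tissue, "off_ratio": ratio,
                         "n_genes": ns[grp], **pvals})
    return pd.DataFrame(rows)


def pair_divergence(assignments: Sequence[TONAssignment],
                    expression: pd.DataFrame) -> pd.DataFrame:
    """Expression divergence |log2((FPKM_a+1)/(FPKM_b+1))| and pair mean
    FPKM per group per tissue, with pairwise Welch t tests between groups
    (BH-corrected across tissues × comparisons)."""
    from statsmodels.stats.multitest import multipletests

    per_pair = []
    for a in assignments:
        if a.gene_a not in expression.index or a.gene_b not in expression.index:
            continue
        fa = expression.loc[a.gene_a].to_numpy(float)
        fb = expression.loc[a.gene_b].to_numpy(float)
        fc = np.abs(np.log2((fa + 1.0) / (fb + 1.0)))
        for t_idx, tissue in enumerate(expression.columns):
            per_pair.append((a.group, tissue, fc[t_idx],
                             (fa[t_idx] + fb[t_idx]) / 2.0))
    pp = pd.DataFrame(per_pair, columns=["group", "tissue", "abs_log2fc",
                                         "mean_fpkm"])
    stats_rows = []
    tests = []
    for tissue, sub in pp.groupby("tissue"):
        means = sub.groupby("group").agg(
            mean_abs_log2fc=("abs_log2fc", "mean"),
            mean_fpkm=("mean_fpkm", "mean"),
            n_pairs=("abs_log2fc", "size"),
        )
        for grp in means.index:
            stats_rows.append({"group": grp, "tissue": tissue,
                               **means.loc[grp].to_dict()})
        for g1, g2 in itertools.combinations(sorted(sub["group"].unique()), 2):
            x = sub.loc[sub["group"] == g1, "abs_log2fc"]
            y = sub.loc[sub["group"] == g2, "abs_log2fc"]
            if len(x) > 1 and len(y) > 1:
                p = stats.ttest_ind(x, y, equal_var=False).pvalue
            else:
                p = float("nan")
            tests.append({"tissue": tissue, "comparison": f"{g1}_vs_{g2}",
                          "p_welch": float(p)})
    stats_df = pd.DataFrame(stats_rows)
    tests_df = pd.DataFrame(tests)
    if len(tests_df) and tests_df["p_welch"].notna().any():
        mask = tests_df["p_welch"].notna()
        adj = multipletests(tests_df.loc[mask, "p_welch"], method="fdr_bh")[1]
        tests_df.loc[mask, "p_welch_bh"] = adj
    stats_df.attrs["pairwise_tests"] = tests_df
    return stats_df


def group_counts(assignments: Sequence[TONAssignment]) -> dict[str, int]:
    out = {"T": 0, "O": 0, "N": 0}
    for a in assignments:
        out[a.group] += 1
    return out
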