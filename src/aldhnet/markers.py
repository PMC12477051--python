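"""Marker derivation: anchor-gene sample split, differential expression,
cross-dataset intersection, and the module correlation matrix.

The discovery route mirrors how the 8-gene module was found: samples are
split into anchor-positive and anchor-negative by 1-D k-means (k = 2) on the
anchor gene's expression, differential genes are called per dataset with a
rank-sum test plus Benjamini–Hochberg correction and a log2 fold-change
floor, the per-dataset marker sets are intersected, and the resulting module
is summarised by its Spearman correlation matrix.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kmeans_anchor_split",
    "differential_genes",
    "intersect_marker_sets",
    "correlation_matrix",
    "read_gmt",
    "write_gmt",
]


def kmeans_anchor_split(
    expr: pd.DataFrame, anchor_gene: str = "ALDH1A3", seed: int = 0
) -> pd.Series:
    """Label samples positive/negative by k-means (k = 2) on one gene.

    The cluster with the higher centroid is "positive" regardless of the
    arbitrary k-means cluster ids.
    """
    if anchor_gene not in expr.index:
        raise KeyError(f"anchor gene {anchor_gene!r} not in expression matrix")
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    v = expr.loc[anchor_gene].to_numpy(dtype=float)
    if np.unique(v).size == 1:
        raise ValueError("anchor gene expression is constant; cannot split")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(v.reshape(-1, 1))
    hi = int(np.argmax(km.cluster_centers_.ravel()))
    labels = np.where(km.labels_ == hi, "positive", "negative")
    return pd.Series(labels, index=expr.columns, name="anchor_label")


def differential_genes(
    expr: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Rank-sum differential expression between two labelled groups.

    Genes pass when the Benjamini–Hochberg adjusted Wilcoxon rank-sum p-value
    is below ``alpha`` and the absolute mean log2 difference
    (positive − negative) is at least ``lfc_min``.

    Returns a frame indexed by gene with ``lfc``, ``p``, ``padj``,
    ``direction`` (up/down relative to the positive group) and the boolean
    ``significant`` flag.
    """
    labels = labels.reindex(expr.columns)
    groups = labels.dropna().unique()
    if len(groups) != 2:
        raise ValueError("labels must define exactly two groups")
    pos_name = "positive" if "positive" in groups else sorted(groups)[0]
    neg_name = [g for g in groups if g != pos_name][0]
    pos = expr.loc[:, labels == pos_name].to_numpy(dtype=float)
    neg = expr.loc[:, labels == neg_name].to_numpy(dtype=float)
    if pos.shape[1] < 3 or neg.shape[1] < 3:
        raise ValueError("each group needs at least 3 samples")

    res = stats.mannwhitneyu(pos, neg, axis=1, alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=float)
    lfc = pos.mean(axis=1) - neg.mean(axis=1)
    padj = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "lfc": lfc,
            "p": pvals,
            "padj": padj,
            "direction": np.where(lfc >= 0, "up", "down"),
        },
        index=expr.index,
    )
    out["significant"] = (out["padj"] < alpha) & (out["lfc"].abs() >= lfc_min)
    return out


def intersect_marker_sets(sets: dict[str, set[str]]) -> dict:
    """Exact k-way intersection with all Venn region cardinalities.

    Region keys are '+'-joined sorted subsets of the set names; each gene is
    counted in exactly one region (its full membership pattern), so region
    counts sum to the size of the union.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 marker sets")
    names = sorted(sets)
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions["+".join(combo)] = 0
    for gene in set().union(*sets.values()):
        pattern = tuple(n for n in names if gene in sets[n])
        regions["+".join(pattern)] += 1
    consensus = set.intersection(*(set(sets[n]) for n in names))
    return {"consensus": consensus, "regions": regions}


def correlation_matrix(expr: pd.DataFrame, genes: list[str]) -> dict:
    """Spearman correlation matrix of a gene module with BH-adjusted p-values.

    Returns ``rho`` (genes × genes, unit diagonal) and ``padj`` where the
    off-diagonal p-values are adjusted jointly across the gene pairs.
    """
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes missing from expression matrix: {missing}")
    if expr.shape[1] < 5:
        raise ValueError("need at least 5 samples")
    sub = expr.loc[genes].to_numpy(dtype=float)
    rho, p = stats.spearmanr(sub, axis=1)
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[np.nan, float(p)], [float(p), np.nan]])
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    np.fill_diagonal(rho, 1.0)
    iu = np.triu_indices(len(genes), k=1)
    padj_flat = multipletests(p[iu], method="fdr_bh")[1]
    padj = np.full_like(p, np.nan)
    padj[iu] = padj_flat
    padj.T[iu] = padj_flat
    return {
        "rho": pd.DataFrame(rho, index=genes, columns=genes),
        "padj": pd.DataFrame(padj, index=genes, columns=genes),
    }


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "aldhnet") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
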