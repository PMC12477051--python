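"""Molecular-subtype classification by NMF on signature genes, consensus
aggressiveness across schemes, and association with score groups.

Each classification scheme is a named set of per-subtype gene lists with a
cluster count k and a designated unfavourable ("aggressive") subtype.
Samples are clustered by rank-k non-negative matrix factorisation of the
signature-gene submatrix (best of several random restarts by reconstruction
error) and clusters are named by matching their centroids to the subtype
signature indicator vectors under a one-to-one maximum-correlation
assignment.  A sample is consensus-aggressive when at least ``threshold``
schemes (default 3) call it unfavourable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF

from .simulate import AGGRESSIVE_LABELS, SIGNATURE_BLOCKS

__all__ = [
    "SignatureScheme",
    "default_schemes",
    "nmf_classify",
    "map_clusters_to_subtypes",
    "classify_scheme",
    "consensus_aggressive",
    "association_tests",
]


@dataclass(frozen=True)
class SignatureScheme:
    """A subtype classification scheme: k disjoint per-subtype gene lists."""

    name: str
    subtype_genes: dict[str, tuple[str, ...]]
    aggressive_label: str

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("scheme needs k >= 2 subtypes")
        all_genes = [g for gl in self.subtype_genes.values() for g in gl]
        if not all_genes or any(not gl for gl in self.subtype_genes.values()):
            raise ValueError("every subtype needs a non-empty gene list")
        if len(set(all_genes)) != len(all_genes):
            raise ValueError("subtype gene lists must be disjoint within a scheme")
        if self.aggressive_label not in self.subtype_genes:
            raise ValueError(
                f"aggressive label {self.aggressive_label!r} not a subtype"
            )

    @property
    def k(self) -> int:
        return len(self.subtype_genes)

    @property
    def genes(self) -> list[str]:
        return [g for gl in self.subtype_genes.values() for g in gl]


def default_schemes() -> list[SignatureScheme]:
    """The three synthetic schemes matching the cohort generator's blocks."""
    return [
        SignatureScheme(
            name=name,
            subtype_genes={lbl: tuple(gl) for lbl, gl in blocks.items()},
            aggressive_label=AGGRESSIVE_LABELS[name],
        )
        for name, blocks in SIGNATURE_BLOCKS.items()
    ]


def nmf_classify(
    expr: pd.DataFrame,
    scheme: SignatureScheme,
    seed: int = 0,
    n_restarts: int = 20,
    min_gene_overlap: int = 10,
) -> pd.Series:
    """Cluster samples by rank-k NMF of the signature-gene submatrix.

    The factorisation with the lowest Frobenius reconstruction error over
    ``n_restarts`` random initialisations is kept; each sample is assigned to
    the component with the largest coefficient.  Cluster ids are arbitrary
    until mapped to subtype names.
    """
    matched = [g for g in scheme.genes if g in expr.index]
    if len(matched) < min_gene_overlap:
        raise ValueError(
            f"only {len(matched)} of {len(scheme.genes)} scheme genes have a "
            f"unique match in the expression matrix (need >= {min_gene_overlap})"
        )
    X = expr.loc[matched].to_numpy(dtype=float)
    if X.min() < 0:  # NMF needs non-negative input
        X = X - X.min()
    best_H, best_err = None, np.inf
    seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    for s in seeds:
        model = NMF(
            n_components=scheme.k,
            init="random",
            random_state=int(s),
            max_iter=2000,
            tol=1e-5,
        )
        W = model.fit_transform(X)
        err = model.reconstruction_err_
        if err < best_err:
            best_err, best_H = err, model.components_
    labels = np.argmax(best_H, axis=0)
    return pd.Series(labels, index=expr.columns, name=f"{scheme.name}_cluster")


def map_clusters_to_subtypes(
    expr: pd.DataFrame, clusters: pd.Series, scheme: SignatureScheme
) -> dict[int, str]:
    """Name NMF clusters by matching centroids to subtype signatures.

    For each cluster the centroid over the scheme's matched genes is
    correlated (Pearson) with each subtype's indicator vector (1 on its own
    genes, 0 elsewhere); clusters get subtype names under the one-to-one
    assignment maximising total correlation.
    """
    matched = [g for g in scheme.genes if g in expr.index]
    cluster_ids = sorted(clusters.unique())
    if len(cluster_ids) != scheme.k:
        raise ValueError(
            f"{len(cluster_ids)} clusters cannot be mapped to {scheme.k} subtypes"
        )
    sub = expr.loc[matched]
    centroids = np.column_stack(
        [sub.loc[:, clusters == c].mean(axis=1).to_numpy() for c in cluster_ids]
    )
    if np.any(np.std(centroids, axis=0) == 0):
        raise ValueError("degenerate (constant) cluster centroid")
    subtype_names = list(scheme.subtype_genes)
    indicators = np.column_stack(
        [
            np.array([1.0 if g in set(scheme.subtype_genes[s]) else 0.0 for g in matched])
            for s in subtype_names
        ]
    )
    corr = np.zeros((len(cluster_ids), len(subtype_names)))
    for i in range(len(cluster_ids)):
        for j in range(len(subtype_names)):
            corr[i, j] = np.corrcoef(centroids[:, i], indicators[:, j])[0, 1]
    row, col = linear_sum_assignment(-corr)
    return {cluster_ids[i]: subtype_names[j] for i, j in zip(row, col)}


def classify_scheme(
    expr: pd.DataFrame,
    scheme: SignatureScheme,
    seed: int = 0,
    n_restarts: int = 20,
) -> pd.Series:
    """NMF clustering plus centroid-based subtype naming in one step."""
    clusters = nmf_classify(expr, scheme, seed=seed, n_restarts=n_restarts)
    mapping = map_clusters_to_subtypes(expr, clusters, scheme)
    return clusters.map(mapping).rename(scheme.name)


def consensus_aggressive(
    calls: pd.DataFrame, schemes: list[SignatureScheme], threshold: int = 3
) -> pd.DataFrame:
    """Flag samples called unfavourable by at least ``threshold`` schemes.

    ``calls`` holds one column of subtype labels per scheme (column name =
    scheme name).  Returns ``aggressive_count`` and ``consensus_aggressive``
    per sample.
    """
    if threshold > len(schemes):
        raise ValueError(
            f"threshold {threshold} exceeds the {len(schemes)} available schemes"
        )
    count = pd.Series(0, index=calls.index)
    for scheme in schemes:
        if scheme.name not in calls.columns:
            raise KeyError(f"calls missing column for scheme {scheme.name!r}")
        count = count + (calls[scheme.name] == scheme.aggressive_label).astype(int)
    return pd.DataFrame(
        {
            "aggressive_count": count,
            "consensus_aggressive": count >= threshold,
        }
    )


def association_tests(groups, flags, scores) -> dict:
    """Association of score groups with consensus aggressiveness.

    Builds the 2×2 table of High/Low score group versus aggressive flag and
    tests it with a chi-squared test without continuity correction, falling
    back to Fisher's exact test when any expected cell is below 5; also runs
    a Welch t-test of the numeric scores by aggressive flag.
    """
    g = pd.Series(groups).astype(str)
    f = pd.Series(flags).astype(bool)
    s = pd.Series(scores, dtype=float)
    table = np.array(
        [
            [(g.eq("High") & f).sum(), (g.eq("High") & ~f).sum()],
            [(g.eq("Low") & f).sum(), (g.eq("Low") & ~f).sum()],
        ],
        dtype=float,
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        raise ValueError("degenerate margin in the 2x2 table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(table)
        test, statistic = "fisher", np.nan
    else:
        statistic, p, _, _ = stats.chi2_contingency(table, correction=False)
        test = "chi2"
    t_stat, t_p = stats.ttest_ind(
        s[f.to_numpy()], s[~f.to_numpy()], equal_var=False
    )
    return {
        "table": table.astype(int),
        "test": test,
        "statistic": float(statistic) if np.isfinite(statistic) else None,
        "p": float(p),
        "t_statistic": float(t_stat),
        "t_p": float(t_p),
    }
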