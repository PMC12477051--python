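"""Per-sample network score: dichotomise each gene at the cohort median rank,
weight the ±1 indicators by the network coefficients, and split the cohort at
the median score.

Each gene contributes +1 for a sample in the top half of its expression across
the cohort and −1 for the bottom half; the score is the coefficient-weighted
sum, so it lies in [−1, +1].  Because the indicators depend only on ranks, any
strictly increasing per-gene transform of the expression leaves scores and
groups unchanged.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .network import CoefficientVector

__all__ = [
    "dichotomize_gene",
    "compute_scores",
    "assign_groups",
    "read_expression_tsv",
    "write_expression_tsv",
]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples expression matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in expression matrix")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in expression matrix")
    return df


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def dichotomize_gene(values, tie_policy: str = "low") -> np.ndarray:
    """Map one gene's per-sample expression to ±1 indicators.

    The ``floor(n/2)`` lowest-ranked samples get −1 and the rest +1, so with
    odd n the +1 half is one sample larger.  Ties are broken by stable sample
    order: under ``tie_policy="low"`` the earlier of tied samples takes the
    lower rank, under ``"high"`` the later one does.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    if np.unique(v).size == 1:
        raise ValueError(
            "constant expression vector: all ranks tied; choose a tie policy "
            "or drop the gene"
        )
    if tie_policy == "low":
        order = np.argsort(v, kind="stable")
    elif tie_policy == "high":
        # later samples among ties get the lower rank
        order = (n - 1) - np.argsort(v[::-1], kind="stable")
    else:
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    indicators = np.ones(n, dtype=int)
    indicators[order[: n // 2]] = -1
    return indicators


def compute_scores(
    expr: pd.DataFrame,
    coefficients: CoefficientVector,
    tie_policy: str = "low",
    group_tie_policy: str = "low",
) -> pd.DataFrame:
    """Compute the weighted network score for every sample.

    Parameters
    ----------
    expr
        Genes-by-samples expression matrix containing all coefficient genes.
    coefficients
        Per-gene coefficients summing to 1.

    Returns
    -------
    DataFrame indexed by sample with one ``ind_<gene>`` column per network
    gene, the weighted ``score`` and the median-split ``group`` (High/Low).
    """
    genes = list(coefficients.genes)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"expression matrix is missing network genes: {missing}")
    out = pd.DataFrame(index=expr.columns)
    score = np.zeros(expr.shape[1])
    for g in genes:
        ind = dichotomize_gene(expr.loc[g].to_numpy(), tie_policy=tie_policy)
        out[f"ind_{g}"] = ind
        score = score + ind * coefficients[g]
    out["score"] = score
    out["group"] = assign_groups(score, tie_policy=group_tie_policy)
    return out


def assign_groups(scores, tie_policy: str = "low") -> np.ndarray:
    """Split samples into High/Low at the median score.

    Samples strictly above the median are High, strictly below are Low;
    samples exactly at the median go to Low under the default policy
    (conservative toward the high-risk call) or to High under ``"high"``.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 samples to assign groups")
    if tie_policy not in ("low", "high"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    med = np.median(s)
    if np.all(s == s[0]):
        warnings.warn("all scores equal; every sample assigned by tie policy")
    groups = np.where(s > med, "High", "Low")
    at_median = s == med
    groups[at_median] = "High" if tie_policy == "high" else "Low"
    groups[s > med] = "High"
    groups[s < med] = "Low"
    return groups
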