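"""Peak→gene annotation and multi-omics intersection arithmetic.

Peaks (BED, 0-based half-open) are assigned to the gene with the nearest
transcription start site (TSS) measured from the peak midpoint, with a
strand-aware signed distance (upstream of the TSS is negative).  Each peak
gets exactly one feature class under the precedence
promoter > exonic > intronic > distal intergenic, where "promoter" means the
midpoint lies within a configurable window of the assigned TSS (default
±2 kb).  On top of the annotation sit the integration statistics: the
TSS-distance profile, a chi-squared comparison of genomic feature
distributions, the fraction of differentially expressed genes carrying a
differential peak, and exact k-way intersections of named gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FEATURE_CLASSES",
    "AnnotatedPeaks",
    "annotate_peaks",
    "tss_distance_profile",
    "feature_distribution_test",
    "overlap_fraction",
    "multiway_intersection",
    "promoter_peak_genes",
]

FEATURE_CLASSES = ("promoter", "exonic", "intronic", "distal intergenic")


@dataclass(frozen=True)
class AnnotatedPeaks:
    """Per-peak nearest-gene assignment with distances and feature classes."""

    table: pd.DataFrame  # columns: chrom, start, end, name, gene, distance, feature

    @property
    def assigned(self) -> pd.DataFrame:
        return self.table[self.table["gene"].notna()]


def annotate_peaks(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    promoter_window: int = 2000,
    exons: dict[str, list[tuple[int, int]]] | None = None,
) -> AnnotatedPeaks:
    """Assign each peak to the gene with the nearest TSS.

    Parameters
    ----------
    peaks
        BED-like frame with ``chrom``, ``start``, ``end`` (0-based half-open)
        and optionally ``name``.
    annotation
        Gene records with ``gene``, ``chrom``, ``strand``, ``tss``,
        ``body_start``, ``body_end``.
    promoter_window
        Half-width (bp) of the promoter window around the TSS.
    exons
        Optional gene → list of (start, end) exon intervals; without it the
        exonic class is never assigned and peaks inside a gene body are
        classed intronic.

    Peaks on chromosomes absent from the annotation stay unassigned with a
    warning.  Distances are signed strand-aware: negative upstream of the
    TSS, positive downstream.
    """
    if annotation.empty:
        raise ValueError("gene annotation is empty")
    required = {"gene", "chrom", "strand", "tss", "body_start", "body_end"}
    if not required <= set(annotation.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")

    by_chrom: dict[str, pd.DataFrame] = {}
    for chrom, sub in annotation.groupby("chrom"):
        by_chrom[chrom] = sub.sort_values("tss", kind="stable").reset_index(drop=True)

    rows = []
    n_unassigned = 0
    for rec in peaks.itertuples(index=False):
        mid = (int(rec.start) + int(rec.end)) // 2
        sub = by_chrom.get(rec.chrom)
        name = getattr(rec, "name", None)
        if sub is None:
            n_unassigned += 1
            rows.append((rec.chrom, rec.start, rec.end, name, None, np.nan, None))
            continue
        tss = sub["tss"].to_numpy()
        j = np.searchsorted(tss, mid)
        best, best_d = None, np.inf
        for k in (j - 1, j):
            if 0 <= k < len(sub) and abs(mid - tss[k]) < best_d:
                best, best_d = k, abs(mid - tss[k])
        gene = sub.iloc[best]
        signed = mid - int(gene.tss)
        if gene.strand == "-":
            signed = -signed
        feature = _feature_class(
            mid, gene, abs(signed), promoter_window, exons
        )
        rows.append((rec.chrom, rec.start, rec.end, name, gene.gene, signed, feature))

    if n_unassigned:
        warnings.warn(
            f"{n_unassigned} peak(s) on chromosomes absent from the annotation "
            "left unassigned"
        )
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "gene", "distance", "feature"],
    )
    return AnnotatedPeaks(table=table)


def _feature_class(mid, gene, abs_dist, promoter_window, exons) -> str:
    if abs_dist <= promoter_window:
        return "promoter"
    in_body = int(gene.body_start) <= mid < int(gene.body_end)
    if in_body and exons is not None:
        for s, e in exons.get(gene.gene, ()):
            if s <= mid < e:
                return "exonic"
    if in_body:
        return "intronic"
    return "distal intergenic"


def tss_distance_profile(annotated: AnnotatedPeaks) -> dict:
    """Median, deciles and log10-binned histogram of |distance to TSS|.

    Histogram bin edges sit at integer powers of 10, with one extra [0, 1)
    bin for peaks sitting exactly at a TSS.
    """
    d = annotated.assigned["distance"].abs().to_numpy(dtype=float)
    if d.size == 0:
        raise ValueError("no assigned peaks")
    top = int(np.floor(np.log10(max(d.max(), 1.0)))) + 1
    edges = np.concatenate(([0.0], np.power(10.0, np.arange(0, top + 1))))
    counts, _ = np.histogram(d, bins=edges)
    return {
        "median": float(np.median(d)),
        "deciles": {
            f"q{10 * i}": float(np.percentile(d, 10 * i)) for i in range(1, 10)
        },
        "histogram": {
            f"[{edges[i]:g},{edges[i + 1]:g})": int(counts[i])
            for i in range(len(counts))
        },
    }


def feature_distribution_test(
    classes_a: dict[str, int] | pd.Series, classes_b: dict[str, int] | pd.Series
) -> dict:
    """Chi-squared test comparing two genomic feature-class distributions.

    Categories with expected count zero in both groups are collapsed away
    with a warning before the test.
    """
    a = pd.Series(classes_a, dtype=float).reindex(FEATURE_CLASSES, fill_value=0.0)
    b = pd.Series(classes_b, dtype=float).reindex(FEATURE_CLASSES, fill_value=0.0)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("both count vectors must have positive totals")
    keep = (a + b) > 0
    if not keep.all():
        warnings.warn("collapsing feature classes with zero counts in both groups")
        a, b = a[keep], b[keep]
    table = np.vstack([a.to_numpy(), b.to_numpy()])
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {"statistic": float(chi2), "df": int(dof), "p": float(p)}


def promoter_peak_genes(
    annotated: AnnotatedPeaks, feature: str = "promoter"
) -> set[str]:
    """Genes carrying at least one peak of the given feature class."""
    tab = annotated.assigned
    return set(tab.loc[tab["feature"] == feature, "gene"])


def overlap_fraction(de_genes: set[str], peak_genes: set[str]) -> dict:
    """Fraction of a DE gene set that also carries a differential peak."""
    de = set(de_genes)
    if not de:
        raise ValueError("DE gene set is empty")
    overlap = de & set(peak_genes)
    return {
        "overlap": len(overlap),
        "total": len(de),
        "fraction": len(overlap) / len(de),
    }


def multiway_intersection(
    named_sets: dict[str, set[str]], min_sets: int = None
) -> pd.DataFrame:
    """Genes present in at least ``min_sets`` of the named sets.

    Returns one row per candidate gene with a boolean membership column per
    input set and the membership count, sorted by descending count then gene
    name.  ``min_sets`` defaults to the number of sets (strict intersection).
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets")
    if min_sets is None:
        min_sets = len(named_sets)
    universe = sorted(set().union(*named_sets.values()))
    rows = []
    for g in universe:
        member = {name: g in s for name, s in named_sets.items()}
        count = sum(member.values())
        if count >= min_sets:
            rows.append({"gene": g, **member, "n_sets": count})
    df = pd.DataFrame(rows, columns=["gene", *named_sets, "n_sets"])
    if not df.empty:
        df = df.sort_values(
            ["n_sets", "gene"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return df
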