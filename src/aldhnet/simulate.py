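"""Synthetic cohorts, survival tables and genomic fixtures.

The generators emit data with the statistical structure the downstream stages
assume, so the whole pipeline can be exercised without restricted-access
cohorts:

* ``simulate_cohort`` — a two-subtype expression cohort (log2 scale) in which
  the 8 network genes share a latent basal-like factor (closed-form pairwise
  correlation) and are shifted upward in basal-like samples, plus planted
  signature-gene blocks for the k = 2/3/4 subtype schemes.
* ``simulate_survival`` — exponential event times with a group-dependent
  hazard and independent exponential censoring.
* ``simulate_peaks`` — a toy genome with non-overlapping stranded genes, a
  designated differentially-expressed (DE) gene subset, and peaks planted so
  that an exact, chosen fraction of DE genes carries a peak within a window
  of its transcription start site (TSS); the remaining peaks fall outside
  every TSS window.

All randomness flows from one integer seed per spec through independent
``numpy`` sub-streams, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import NETWORK_GENES

__all__ = [
    "CohortSpec",
    "SurvivalSpec",
    "PeakSimSpec",
    "SIGNATURE_BLOCKS",
    "simulate_cohort",
    "simulate_survival",
    "simulate_peaks",
    "write_survival_tsv",
    "write_peaks_bed",
    "write_gene_annotation_tsv",
    "read_gene_annotation_tsv",
    "read_peaks_bed",
]


def _signature_blocks() -> dict[str, dict[str, list[str]]]:
    """Planted signature-gene blocks for the three subtype schemes.

    Scheme names follow the published PDAC classification families: a 2-class
    basal-like/classical scheme, a 3-class scheme whose aggressive arm is
    quasi-mesenchymal, and a 4-class scheme whose aggressive arm is squamous.
    """
    def genes(prefix: str, n: int) -> list[str]:
        return [f"{prefix}_{i:03d}" for i in range(1, n + 1)]

    return {
        "two_class": {
            "basal-like": genes("SIG2_BAS", 24),
            "classical": genes("SIG2_CLA", 24),
        },
        "three_class": {
            "quasi-mesenchymal": genes("SIG3_QM", 21),
            "classical": genes("SIG3_CLA", 20),
            "exocrine-like": genes("SIG3_EXO", 20),
        },
        "four_class": {
            "squamous": genes("SIG4_SQ", 25),
            "progenitor": genes("SIG4_PRO", 25),
            "immunogenic": genes("SIG4_IMM", 25),
            "ADEX": genes("SIG4_ADX", 25),
        },
    }


SIGNATURE_BLOCKS: dict[str, dict[str, list[str]]] = _signature_blocks()

#: Which subtype of each scheme is the unfavourable (aggressive) one.
AGGRESSIVE_LABELS: dict[str, str] = {
    "two_class": "basal-like",
    "three_class": "quasi-mesenchymal",
    "four_class": "squamous",
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic two-subtype expression cohort."""

    n_samples: int = 200
    n_background_genes: int = 300
    subtype_fraction: float = 0.4  # fraction of basal-like samples
    module_effect: float = 2.0  # log2 shift of network/signature genes
    module_correlation: float = 0.6  # target pairwise corr. of the 8-gene module
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 8:
            raise ValueError("n_samples must be >= 8")
        if not 0.0 < self.subtype_fraction < 1.0:
            raise ValueError("subtype_fraction must be in (0, 1)")
        if not 0.0 <= self.module_correlation < 1.0:
            raise ValueError("module_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")


@dataclass(frozen=True)
class SurvivalSpec:
    """Exponential survival with a multiplicative group hazard."""

    baseline_hazard: float = 0.05
    hazard_ratio: float = 2.5
    censor_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")


@dataclass(frozen=True)
class PeakSimSpec:
    """Toy genome with planted TSS-proximal peaks on a DE-gene subset."""

    n_chromosomes: int = 4
    chrom_length: int = 30_000_000
    n_genes: int = 1500
    n_peaks: int = 2000
    n_de_genes: int = 709
    planted_overlap_fraction: float = 0.58
    tss_window: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.planted_overlap_fraction <= 1.0:
            raise ValueError("planted_overlap_fraction must be in [0, 1]")
        if self.tss_window <= 0:
            raise ValueError("tss_window must be > 0")
        if self.n_genes < self.n_de_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if min(self.n_chromosomes, self.chrom_length, self.n_genes, self.n_peaks) <= 0:
            raise ValueError("counts and lengths must be positive")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Derive n independent generators from one integer seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# expression cohort
# ---------------------------------------------------------------------------

def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a genes-by-samples log2 expression matrix plus true labels.

    The 8 network genes follow a one-factor Gaussian model: gene g in sample
    s is ``loading * f_s + sqrt(1 - rho) * eps`` with ``loading = sqrt(rho)``,
    scaled by ``noise_sd``, so that (with no subtype shift) every pair of
    module genes has Pearson correlation exactly ``rho``.  Basal-like samples
    additionally get ``module_effect`` added to the network genes and to the
    aggressive-arm signature block of each scheme; non-basal samples express
    one of the non-aggressive blocks of each scheme instead.

    Values are clipped at zero so the matrix is directly usable as NMF input.
    """
    spec.validate()
    rng_lbl, rng_base, rng_noise, rng_mod, rng_blocks = _streams(spec.seed, 5)

    n = spec.n_samples
    n_basal = int(round(spec.subtype_fraction * n))
    n_basal = min(max(n_basal, 1), n - 1)  # both subtypes present
    labels = np.array(["classical"] * n, dtype=object)
    basal_idx = rng_lbl.choice(n, size=n_basal, replace=False)
    labels[basal_idx] = "basal-like"
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    truth = pd.Series(labels, index=samples, name="subtype")
    is_basal = labels == "basal-like"

    gene_names: list[str] = list(NETWORK_GENES)
    for scheme in SIGNATURE_BLOCKS.values():
        for gl in scheme.values():
            gene_names.extend(gl)
    gene_names.extend(f"BG{i:05d}" for i in range(1, spec.n_background_genes + 1))

    base = rng_base.uniform(3.0, 10.0, size=len(gene_names))
    expr = base[:, None] + rng_noise.normal(0.0, spec.noise_sd, (len(gene_names), n))
    expr = pd.DataFrame(expr, index=gene_names, columns=samples)

    # latent basal-like factor shared by the 8 network genes
    rho = spec.module_correlation
    f = rng_mod.normal(0.0, 1.0, n)
    for g in NETWORK_GENES:
        eps = rng_mod.normal(0.0, 1.0, n)
        module_part = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * eps
        # replace the independent noise by the correlated one, same variance
        expr.loc[g] = base[gene_names.index(g)] + spec.noise_sd * module_part
    expr.loc[list(NETWORK_GENES), is_basal] += spec.module_effect

    # planted signature blocks: each sample expresses one subtype block per scheme
    for scheme_name, blocks in SIGNATURE_BLOCKS.items():
        aggressive = AGGRESSIVE_LABELS[scheme_name]
        others = [lbl for lbl in blocks if lbl != aggressive]
        per_sample = np.where(
            is_basal, aggressive, rng_blocks.choice(others, size=n)
        )
        for lbl, genes in blocks.items():
            cols = per_sample == lbl
            if cols.any():
                expr.loc[genes, cols] += spec.module_effect

    expr = expr.clip(lower=0.0)
    return expr, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(groups, spec: SurvivalSpec) -> pd.DataFrame:
    """Simulate (time, event) per sample from a two-group exponential model.

    ``groups`` is a per-sample binary/boolean label (1 = elevated hazard); a
    pandas Series index is carried through as the sample id.
    """
    spec.validate()
    g = pd.Series(groups)
    if g.empty:
        raise ValueError("groups must be non-empty")
    flag = g.astype(float).to_numpy()
    if not np.isin(flag, [0.0, 1.0]).all():
        raise ValueError("groups must be binary (0/1)")
    rng_event, rng_cens = _streams(spec.seed, 2)
    hazard = spec.baseline_hazard * np.where(flag == 1.0, spec.hazard_ratio, 1.0)
    t_event = rng_event.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        t_cens = rng_cens.exponential(1.0 / spec.censor_rate, size=len(g))
    else:
        t_cens = np.full(len(g), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    index = g.index if isinstance(groups, pd.Series) else pd.RangeIndex(len(g))
    return pd.DataFrame(
        {"sample": index, "time": time, "event": event, "group": flag.astype(int)}
    ).set_index("sample")


# ---------------------------------------------------------------------------
# peaks / annotation
# ---------------------------------------------------------------------------

def simulate_peaks(
    spec: PeakSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Generate (peaks, gene annotation, DE gene set) on a toy genome.

    Genes are laid out in equal non-overlapping slots per chromosome with a
    gap of at least ``2 * tss_window + 1`` between neighbouring TSSs, so a
    peak planted within one gene's TSS window is always nearest to that gene.
    Exactly ``round(f * n_de_genes)`` DE genes receive a planted peak with
    midpoint inside TSS ± tss_window; all remaining peaks are placed outside
    every TSS window.
    """
    spec.validate()
    rng_genes, rng_de, rng_plant, rng_bg = _streams(spec.seed, 4)

    peak_half = 150  # fixed 300 bp peaks
    genes_per_chrom = int(np.ceil(spec.n_genes / spec.n_chromosomes))
    slot = spec.chrom_length // genes_per_chrom
    # margin keeps TSS windows of neighbouring genes disjoint and planted
    # peaks inside chromosome bounds
    margin = spec.tss_window + peak_half + 2
    if slot - 2 * margin < 1500:
        raise ValueError(
            "genome too small: gene slots cannot keep TSS windows disjoint"
        )

    records = []
    gid = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        for s in range(genes_per_chrom):
            if gid >= spec.n_genes:
                break
            lo, hi = s * slot + margin, (s + 1) * slot - margin
            body_len = int(rng_genes.integers(1000, min(20_000, hi - lo - 1)))
            start = int(rng_genes.integers(lo, hi - body_len))
            end = start + body_len
            strand = "+" if rng_genes.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            records.append((f"G{gid + 1:05d}", chrom, strand, tss, start, end))
            gid += 1
    ann = pd.DataFrame(
        records, columns=["gene", "chrom", "strand", "tss", "body_start", "body_end"]
    )

    de_idx = rng_de.choice(len(ann), size=spec.n_de_genes, replace=False)
    de_genes = set(ann.iloc[de_idx]["gene"])
    n_planted = int(round(spec.planted_overlap_fraction * spec.n_de_genes))
    if n_planted > spec.n_peaks:
        raise ValueError("n_peaks too small for the requested planted fraction")
    planted_idx = rng_plant.choice(de_idx, size=n_planted, replace=False)

    peaks = []
    for i, row_i in enumerate(planted_idx):
        row = ann.iloc[row_i]
        offset = int(rng_plant.integers(-(spec.tss_window - 1), spec.tss_window))
        mid = int(row.tss) + offset
        peaks.append(
            (row.chrom, mid - peak_half, mid + peak_half, f"peak_planted_{i + 1}")
        )

    # background peaks: rejection-sample midpoints outside every TSS window
    tss_by_chrom = {
        chrom: np.sort(sub["tss"].to_numpy())
        for chrom, sub in ann.groupby("chrom")
    }
    n_bg = spec.n_peaks - n_planted
    placed = 0
    attempts = 0
    while placed < n_bg:
        attempts += 1
        if attempts > 200 * max(n_bg, 1):
            raise ValueError("could not place background peaks outside TSS windows")
        chrom = f"chr{int(rng_bg.integers(spec.n_chromosomes)) + 1}"
        mid = int(rng_bg.integers(peak_half, spec.chrom_length - peak_half))
        tss = tss_by_chrom.get(chrom)
        if tss is not None and tss.size:
            j = np.searchsorted(tss, mid)
            near = min(
                abs(mid - tss[j - 1]) if j > 0 else np.inf,
                abs(tss[j] - mid) if j < tss.size else np.inf,
            )
            if near <= spec.tss_window:
                continue
        placed += 1
        peaks.append((chrom, mid - peak_half, mid + peak_half, f"peak_bg_{placed}"))

    peak_df = pd.DataFrame(peaks, columns=["chrom", "start", "end", "name"])
    peak_df["score"] = 0
    peak_df["strand"] = "."
    peak_df = peak_df.sort_values(["chrom", "start"], kind="stable").reset_index(
        drop=True
    )
    return peak_df, ann, de_genes


# ---------------------------------------------------------------------------
# plain-text writers / readers
# ---------------------------------------------------------------------------

def write_survival_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.reset_index().to_csv(path, sep="\t", index=False)


def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_gene_annotation_tsv(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_gene_annotation_tsv(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "strand", "tss", "body_start", "body_end"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    return ann
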