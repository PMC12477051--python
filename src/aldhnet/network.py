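"""Connectivity-weighted gene network and per-gene scoring coefficients.

The scoring signature is an 8-gene interaction network around ALDH1A3.  Each
gene receives a non-negative weight ("numerator") reflecting how many network
edges touch it: a bidirectional edge contributes a full unit split between its
endpoints, a directed edge contributes half a unit to its target.  The default
network has 13 edges, so the weights sum to 13 and each gene's scoring
coefficient is its weight divided by 13.

Two published weightings of the same network differ only by swapping the EMP1
and PMEPA1 coefficients; the Methods-derived weighting is the default and the
alternative is available via ``figure1f_weights=True``.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "NETWORK_GENES",
    "DEFAULT_GENE_WEIGHTS",
    "FIGURE1F_GENE_WEIGHTS",
    "Edge",
    "GeneNetwork",
    "CoefficientVector",
    "derive_coefficients",
    "validate_edge_list",
    "default_network",
    "read_network_config",
    "write_coefficients_tsv",
]

NETWORK_GENES: tuple[str, ...] = (
    "ALDH1A3",
    "EMP1",
    "FAM3C",
    "IRS2",
    "MAML2",
    "MCC",
    "PMEPA1",
    "SP100",
)

#: Per-gene numerators over the 13 network edges (Methods-derived default).
DEFAULT_GENE_WEIGHTS: dict[str, float] = {
    "ALDH1A3": 3.0,
    "FAM3C": 2.5,
    "EMP1": 1.5,
    "PMEPA1": 2.0,
    "MCC": 1.5,
    "IRS2": 1.0,
    "MAML2": 1.0,
    "SP100": 0.5,
}

#: Alternative weighting with the EMP1/PMEPA1 numerators exchanged.
FIGURE1F_GENE_WEIGHTS: dict[str, float] = {
    **DEFAULT_GENE_WEIGHTS,
    "EMP1": 2.0,
    "PMEPA1": 1.5,
}


@dataclass(frozen=True)
class Edge:
    """A network edge: ``double`` (bidirectional) or ``single`` (directed).

    For a ``single`` edge, ``gene_b`` is the target of the arrow.
    """

    gene_a: str
    gene_b: str
    kind: str = "double"

    def __post_init__(self) -> None:
        if self.kind not in ("double", "single"):
            raise ValueError(f"edge kind must be 'double' or 'single', got {self.kind!r}")


@dataclass
class GeneNetwork:
    """The scoring network: ordered gene list, per-gene weights, optional edges."""

    genes: tuple[str, ...] = NETWORK_GENES
    gene_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_WEIGHTS)
    )
    edges: tuple[Edge, ...] | None = None

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in network")
        missing = [g for g in self.genes if g not in self.gene_weights]
        if missing:
            raise ValueError(f"gene_weights missing entries for: {missing}")
        if any(w < 0 for w in self.gene_weights.values()):
            raise ValueError("gene_weights must be non-negative")
        if self.total_weight <= 0:
            raise ValueError("total network weight must be positive")
        if self.edges is not None:
            self.edges = tuple(self.edges)
            known = set(self.genes)
            for e in self.edges:
                for g in (e.gene_a, e.gene_b):
                    if g not in known:
                        raise ValueError(f"edge references unknown gene {g!r}")

    @property
    def total_weight(self) -> float:
        return sum(self.gene_weights[g] for g in self.genes)


@dataclass(frozen=True)
class CoefficientVector:
    """Normalised per-gene coefficients; ``percent`` is rounded half-up to 2 dp."""

    coefficients: dict[str, float]
    percent: dict[str, float]

    def __getitem__(self, gene: str) -> float:
        return self.coefficients[gene]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.coefficients)


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def default_network(figure1f_weights: bool = False) -> GeneNetwork:
    """Return the default 8-gene network.

    Parameters
    ----------
    figure1f_weights
        If True, use the variant weighting that swaps the EMP1 and PMEPA1
        numerators (both variants total 13).
    """
    weights = FIGURE1F_GENE_WEIGHTS if figure1f_weights else DEFAULT_GENE_WEIGHTS
    return GeneNetwork(genes=NETWORK_GENES, gene_weights=dict(weights))


def derive_coefficients(network: GeneNetwork) -> CoefficientVector:
    """Normalise per-gene weights into coefficients summing to 1.

    coefficient(g) = weight(g) / total; the percentage form is coefficient
    times 100, rounded half-up to two decimals.
    """
    total = network.total_weight
    if total <= 0:
        raise ValueError("total network weight must be positive")
    coeffs = {g: network.gene_weights[g] / total for g in network.genes}
    percent = {g: _round_half_up(c * 100.0) for g, c in coeffs.items()}
    return CoefficientVector(coefficients=coeffs, percent=percent)


@dataclass(frozen=True)
class EdgeValidationReport:
    reconstructed: dict[str, float] | None
    reconstructed_total: float | None
    mismatches: dict[str, tuple[float, float]]  # gene -> (declared, reconstructed)
    message: str

    @property
    def ok(self) -> bool:
        return not self.mismatches


def validate_edge_list(
    network: GeneNetwork, allocation: str = "split-double-half-single-target"
) -> EdgeValidationReport:
    """Check that the edge list reproduces the declared per-gene weights.

    The default allocation rule gives 0.5 to each endpoint of a bidirectional
    edge and 0.5 to the target of a directed edge — the only allocation family
    under which 13 edges can total 13 weight units on this network.
    """
    if allocation != "split-double-half-single-target":
        raise ValueError(f"unknown allocation rule {allocation!r}")
    if network.edges is None:
        return EdgeValidationReport(
            reconstructed=None,
            reconstructed_total=None,
            mismatches={},
            message="edge list absent; numerators taken as authoritative",
        )
    recon = {g: 0.0 for g in network.genes}
    for e in network.edges:
        if e.kind == "double":
            recon[e.gene_a] += 0.5
            recon[e.gene_b] += 0.5
        else:
            recon[e.gene_b] += 0.5
    mism = {
        g: (network.gene_weights[g], recon[g])
        for g in network.genes
        if abs(network.gene_weights[g] - recon[g]) > 1e-12
    }
    total = sum(recon.values())
    msg = "edge list reproduces declared weights" if not mism else (
        f"{len(mism)} gene(s) mismatch declared weights"
    )
    return EdgeValidationReport(
        reconstructed=recon, reconstructed_total=total, mismatches=mism, message=msg
    )


def read_network_config(path: str | Path) -> GeneNetwork:
    """Load a network from an INI-style config.

    ``[weights]`` maps gene symbol to numerator; an optional ``[edges]``
    section lists edges as ``name = GENE_A,GENE_B,double|single`` (for single,
    the second gene is the arrow target).
    """
    parser = configparser.ConfigParser()
    parser.optionxform = str  # keep gene-symbol case
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(path)
    if "weights" not in parser:
        raise ValueError("network config needs a [weights] section")
    weights = {g: float(v) for g, v in parser["weights"].items()}
    edges = None
    if "edges" in parser:
        edges = []
        for _, spec in parser["edges"].items():
            parts = [p.strip() for p in spec.split(",")]
            if len(parts) != 3:
                raise ValueError(f"bad edge spec {spec!r}; want GENE_A,GENE_B,kind")
            edges.append(Edge(parts[0], parts[1], parts[2]))
        edges = tuple(edges)
    return GeneNetwork(genes=tuple(weights), gene_weights=weights, edges=edges)


def write_coefficients_tsv(coeffs: CoefficientVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcoefficient\tpercent\n")
        for g in coeffs.genes:
            fh.write(f"{g}\t{coeffs.coefficients[g]:.10g}\t{coeffs.percent[g]:.2f}\n")
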