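"""Depth-corrected SNP abundance.

The per-contig statistic ``beta`` rescales the observed per-base SNP count by
the harmonic number of the sequencing depth,

    beta = [(S + 1) / L] / H(D - 1),    H(n) = sum_{i=1}^{n} 1/i,

where ``S`` is the number of SNPs detected in a contig of length ``L``
sequenced at mean depth ``D``.  Under neutral expectations the number of
segregating sites grows with the harmonic number of the number of sequences
sampled, so dividing by ``H(D - 1)`` removes most of the mechanical
association between SNP yield and coverage and leaves a quantity comparable
across contigs sequenced at different depths.

Genes assembled from several contigs receive a sequence-length-weighted mean
of their contig betas.  Ranking genes by that weighted beta and taking the
top decile defines the "most SNPed" gene set used by the enrichment stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import special, stats

from .errors import DomainError

__all__ = [
    "ContigAbundance",
    "GeneAbundance",
    "harmonic_number",
    "beta",
    "gene_beta",
    "aggregate_genes",
    "rank_genes",
    "depth_correlation",
]

DepthMode = Literal["floor", "interpolate"]


@dataclass(frozen=True)
class ContigAbundance:
    """SNP abundance of a single contig: ``S`` SNPs over ``L`` bp at depth ``D``."""

    contig_id: str
    S: int
    L: int
    D: float
    beta: float


@dataclass
class GeneAbundance:
    """Length-weighted gene-level abundance aggregated over contig parts."""

    gene_id: str
    contig_parts: list[ContigAbundance]
    beta_weighted: float
    rank: int | None = None
    top_decile: bool = False

    @property
    def total_snps(self) -> int:
        return sum(p.S for p in self.contig_parts)


def harmonic_number(n: int) -> float:
    """H(n) = 1 + 1/2 + ... + 1/n; H(0) = 0."""
    if n < 0:
        raise DomainError(f"harmonic number undefined for n={n}")
    return float(np.sum(1.0 / np.arange(1, n + 1))) if n > 0 else 0.0


def _harmonic_interpolated(x: float) -> float:
    # H(x) analytically continued: H(x) = digamma(x + 1) + gamma.
    return float(special.digamma(x + 1.0) + np.euler_gamma)


def beta(S: int, L: int, D: float, *, depth_mode: DepthMode = "floor") -> float:
    """Depth-corrected SNP abundance of one contig.

    Parameters
    ----------
    S : number of SNPs detected in the contig (>= 0).
    L : contig length in bp (> 0).
    D : mean read depth of the contig; the harmonic sum runs to ``floor(D) - 1``
        (default) or, with ``depth_mode="interpolate"``, uses the continuous
        harmonic number H(D - 1) via the digamma function.
    """
    if L <= 0:
        raise DomainError(f"contig length must be positive, got L={L}")
    if S < 0:
        raise DomainError(f"SNP count must be non-negative, got S={S}")
    if math.floor(D) < 2:
        raise DomainError(
            f"mean depth D={D} gives an empty harmonic sum (floor(D) must be >= 2)"
        )
    if depth_mode == "floor":
        denom = harmonic_number(math.floor(D) - 1)
    elif depth_mode == "interpolate":
        denom = _harmonic_interpolated(D - 1.0)
    else:  # pragma: no cover - guarded by Literal type
        raise DomainError(f"unknown depth_mode {depth_mode!r}")
    return ((S + 1) / L) / denom


def contig_abundance(
    contig_id: str, S: int, L: int, D: float, *, depth_mode: DepthMode = "floor"
) -> ContigAbundance:
    """Convenience constructor evaluating :func:`beta` for one contig."""
    return ContigAbundance(contig_id, S, L, D, beta(S, L, D, depth_mode=depth_mode))


def gene_beta(parts: Sequence[ContigAbundance]) -> float:
    """Sequence-length-weighted mean beta over a gene's contig parts."""
    if not parts:
        raise DomainError("gene_beta requires at least one contig part")
    total_len = sum(p.L for p in parts)
    return sum(p.L * p.beta for p in parts) / total_len


def aggregate_genes(
    parts_by_gene: dict[str, list[ContigAbundance]]
) -> list[GeneAbundance]:
    """Build one :class:`GeneAbundance` per gene from its contig parts."""
    return [
        GeneAbundance(gene_id=g, contig_parts=list(parts), beta_weighted=gene_beta(parts))
        for g, parts in parts_by_gene.items()
    ]


def rank_genes(
    genes: Iterable[GeneAbundance], decile: float = 0.10
) -> tuple[list[GeneAbundance], set[str]]:
    """Rank genes by descending weighted beta and flag the top decile.

    Ties break on descending total SNP count, then lexicographic gene id, so
    the ranking is deterministic regardless of input order.  The top set holds
    ``floor(decile * N)`` genes (at least one).
    """
    genes = list(genes)
    if not genes:
        raise DomainError("rank_genes requires a non-empty gene list")
    if not 0.0 < decile < 1.0:
        raise DomainError(f"decile must lie in (0, 1), got {decile}")
    ranked = sorted(
        genes, key=lambda g: (-g.beta_weighted, -g.total_snps, g.gene_id)
    )
    n_top = max(1, math.floor(decile * len(ranked)))
    top: set[str] = set()
    for i, g in enumerate(ranked):
        g.rank = i + 1
        g.top_decile = i < n_top
        if g.top_decile:
            top.add(g.gene_id)
    return ranked, top


def depth_correlation(
    contigs: Sequence[ContigAbundance],
) -> tuple[float, float]:
    """Pearson correlations of raw per-bp SNP density (S/L) and beta with depth.

    Returns ``(r_raw, r_beta)``.  With depth-coupled SNP discovery the
    corrected statistic should show the weaker association, ``|r_beta| <
    |r_raw|``.
    """
    if len(contigs) < 3:
        raise DomainError("depth correlation needs at least 3 contigs")
    density = np.array([c.S / c.L for c in contigs])
    betas = np.array([c.beta for c in contigs])
    depth = np.array([c.D for c in contigs])
    if np.ptp(depth) == 0 or np.ptp(density) == 0 or np.ptp(betas) == 0:
        raise DomainError("depth correlation undefined: zero variance in an input")
    r_raw = stats.pearsonr(density, depth).statistic
    r_beta = stats.pearsonr(betas, depth).statistic
    return float(r_raw), float(r_beta)
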