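"""Contig-to-target pairing.

De novo contigs assembled from capture reads are compared (blastn-style)
against the transcript set the capture probes were designed from.  A hit is
retained when it is long enough, similar enough, statistically credible and
sequenced within an acceptable coverage window; each retained contig is then
assigned to a single best gene, and simple recovery statistics are reported
(fraction of targeted genes recovered, contigs per paired gene).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import DomainError

__all__ = [
    "TargetHit",
    "PairingResult",
    "filter_hits",
    "pair_and_summarize",
    "summarize_counts",
]

#: Default retention thresholds: identity >= 95 %, e-value < 1e-5,
#: mean coverage within the closed window [25, 800], contig length > 500 bp.
DEFAULT_MIN_IDENTITY = 95.0
DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_COVERAGE_WINDOW = (25.0, 800.0)
DEFAULT_MIN_LENGTH = 500


@dataclass(frozen=True)
class TargetHit:
    """One contig-vs-target alignment row (a blastn outfmt-6 derived record
    augmented with the contig's mean sequencing coverage)."""

    contig_id: str
    gene_id: str
    identity: float  # percent, in [0, 100]
    evalue: float
    mean_coverage: float
    contig_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise DomainError(f"identity must be in [0,100], got {self.identity}")
        if self.evalue < 0:
            raise DomainError(f"evalue must be >= 0, got {self.evalue}")
        if self.mean_coverage < 0:
            raise DomainError(f"mean_coverage must be >= 0, got {self.mean_coverage}")


@dataclass
class PairingResult:
    retained_hits: list[TargetHit]
    paired_genes: set[str]
    n_contigs_retained: int
    contigs_per_gene: float  # NaN when no gene paired
    recovery_rate: float  # percent of targeted genes recovered; full precision


def hit_passes(
    hit: TargetHit,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    coverage_window: tuple[float, float] = DEFAULT_COVERAGE_WINDOW,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> bool:
    """Single-row retention predicate (identity closed, e-value strict,
    coverage closed window, length strict)."""
    lo, hi = coverage_window
    return (
        hit.identity >= min_identity
        and hit.evalue < max_evalue
        and lo <= hit.mean_coverage <= hi
        and hit.contig_length > min_length
    )


def filter_hits(
    hits: Sequence[TargetHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    coverage_window: tuple[float, float] = DEFAULT_COVERAGE_WINDOW,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[TargetHit]:
    """Apply the retention thresholds row by row, preserving input order."""
    for name, value in (
        ("min_identity", min_identity),
        ("max_evalue", max_evalue),
        ("coverage low", coverage_window[0]),
        ("coverage high", coverage_window[1]),
        ("min_length", min_length),
    ):
        if not math.isfinite(value):
            raise DomainError(f"threshold {name} must be finite, got {value}")
    return [
        h
        for h in hits
        if hit_passes(h, min_identity, max_evalue, coverage_window, min_length)
    ]


def best_gene_assignment(retained: Sequence[TargetHit]) -> dict[str, TargetHit]:
    """Assign each contig to its single best gene.

    Best = lowest e-value, then highest identity, then lexicographically
    smallest gene id, so the assignment is deterministic.
    """
    best: dict[str, TargetHit] = {}
    for hit in retained:
        cur = best.get(hit.contig_id)
        if cur is None or (hit.evalue, -hit.identity, hit.gene_id) < (
            cur.evalue,
            -cur.identity,
            cur.gene_id,
        ):
            best[hit.contig_id] = hit
    return best


def pair_and_summarize(retained: Sequence[TargetHit], n_targeted: int) -> PairingResult:
    """Collapse retained hits to one gene per contig and summarize recovery.

    ``recovery_rate`` is 100 x (paired genes / targeted genes);
    ``contigs_per_gene`` is retained contigs / paired genes.  Ratios are kept
    at full precision; round only when rendering reports.
    """
    if n_targeted <= 0:
        raise DomainError(f"n_targeted must be positive, got {n_targeted}")
    assignment = best_gene_assignment(retained)
    paired_genes = {hit.gene_id for hit in assignment.values()}
    n_contigs = len(assignment)
    if paired_genes:
        contigs_per_gene = n_contigs / len(paired_genes)
    else:
        contigs_per_gene = float("nan")
    recovery = 100.0 * len(paired_genes) / n_targeted
    return PairingResult(
        retained_hits=list(assignment.values()),
        paired_genes=paired_genes,
        n_contigs_retained=n_contigs,
        contigs_per_gene=contigs_per_gene,
        recovery_rate=recovery,
    )


def summarize_counts(
    n_contigs_retained: int, n_paired_genes: int, n_targeted: int
) -> tuple[float, float]:
    """Recovery accounting from bare counts.

    Returns ``(contigs_per_gene, recovery_rate_percent)`` — the same ratios
    :func:`pair_and_summarize` derives, for when only the tallies of a
    completed pairing are available.
    """
    if n_targeted <= 0:
        raise DomainError(f"n_targeted must be positive, got {n_targeted}")
    if n_paired_genes <= 0:
        return float("nan"), 0.0
    return (
        n_contigs_retained / n_paired_genes,
        100.0 * n_paired_genes / n_targeted,
    )
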