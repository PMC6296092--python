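"""Array-marker quality control and true-positive-rate accounting.

Each marker on the genotyping array is classified from its genotype calls
(AA / AB / BB / NoCall) across the genotyped samples:

``other_fail``
    clustering-quality (GenTrain-style) score below 0.13 or call rate below
    80 % — the signal gates applied before any genotype-based curation;
``monomorphic``
    every called sample falls in a single *homozygous* class;
``paralogous``
    large excess of heterozygotes, Fe >= 0.80, the signature of a probe
    annealing to two fixed paralogous loci (an all-heterozygote marker is
    paralogous, not monomorphic);
``valid``
    everything else — a segregating, well-behaved assay.

The heterozygote-excess statistic defaults to

    Fe = (Ho - He) / (1 - He),   He = 2 p (1 - p),

clamped to 0 when Ho <= He; it is 1 for an all-heterozygote marker and 0 at
Hardy-Weinberg proportions.  An alternative parameterization Fe = Ho/He - 1
is available behind a switch; both agree at the extremes that drive
classification.

The true-positive-rate report tallies the four classes per SNP source
(array controls recycled from earlier assays vs newly predicted SNPs); the
success rate of a source is the fraction of its manufactured markers that
yield valid assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InputValidationError

__all__ = [
    "CALL_STATES",
    "GenotypeMatrix",
    "MarkerQC",
    "QcThresholds",
    "TprReport",
    "marker_stats",
    "classify_marker",
    "classify_matrix",
    "replicate_concordance",
    "tpr_report",
    "success_rate",
]

CALL_STATES = ("AA", "AB", "BB", "NC")
Klass = Literal["valid", "monomorphic", "paralogous", "other_fail"]
FeMode = Literal["excess", "ratio"]


@dataclass(frozen=True)
class QcThresholds:
    min_gentrain: float = 0.13
    min_call_rate: float = 0.80
    min_fe: float = 0.80
    fe_mode: FeMode = "excess"


@dataclass
class GenotypeMatrix:
    """Markers x samples genotype calls plus per-marker metadata.

    ``calls`` is a DataFrame indexed by marker id with sample ids as columns
    and entries in {AA, AB, BB, NC}; ``markers`` is indexed identically and
    carries ``gentrain_score`` and ``source`` ({control, predicted});
    ``replicate_pairs`` lists (sample, duplicate-sample) column pairs.
    """

    calls: pd.DataFrame
    markers: pd.DataFrame
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.to_numpy())) - set(CALL_STATES)
        if bad:
            raise InputValidationError(f"unknown genotype states: {sorted(bad)}")
        if not self.calls.index.equals(self.markers.index):
            raise InputValidationError("calls and marker metadata indices differ")
        for a, b in self.replicate_pairs:
            if a not in self.calls.columns or b not in self.calls.columns:
                raise InputValidationError(f"replicate pair ({a}, {b}) not in samples")


@dataclass
class MarkerQC:
    marker_id: str
    call_rate: float
    p: float | None  # allele-A frequency; None when no calls
    Ho: float | None
    He: float | None
    Fe: float | None
    klass: Klass
    gentrain_score: float | None = None
    source: str | None = None


def _fe(Ho: float, He: float, mode: FeMode) -> float:
    if mode == "excess":
        if He >= 1.0:
            return 0.0
        return max(0.0, (Ho - He) / (1.0 - He))
    if mode == "ratio":
        if He == 0.0:
            return 0.0
        return max(0.0, Ho / He - 1.0)
    raise DomainError(f"unknown fe_mode {mode!r}")


def marker_stats(
    calls: Sequence[str], fe_mode: FeMode = "excess"
) -> tuple[float, float | None, float | None, float | None, float | None]:
    """Per-marker summary: (call_rate, p, Ho, He, Fe).

    p = (2 nAA + nAB) / (2 n_called); Ho = nAB / n_called; He = 2p(1-p).
    All frequency statistics are None when every sample is NoCall.
    """
    n_total = len(calls)
    if n_total == 0:
        raise DomainError("marker_stats requires at least one sample")
    n_aa = sum(1 for c in calls if c == "AA")
    n_ab = sum(1 for c in calls if c == "AB")
    n_bb = sum(1 for c in calls if c == "BB")
    n_called = n_aa + n_ab + n_bb
    call_rate = n_called / n_total
    if n_called == 0:
        return call_rate, None, None, None, None
    p = (2 * n_aa + n_ab) / (2 * n_called)
    Ho = n_ab / n_called
    He = 2.0 * p * (1.0 - p)
    return call_rate, p, Ho, He, _fe(Ho, He, fe_mode)


def classify_marker(
    calls: Sequence[str],
    gentrain: float,
    thresholds: QcThresholds = QcThresholds(),
) -> MarkerQC:
    """Classify one marker; precedence: signal gates, monomorphism, Fe, valid."""
    call_rate, p, Ho, He, Fe = marker_stats(calls, thresholds.fe_mode)
    if p is None:
        klass: Klass = "other_fail"
    elif gentrain < thresholds.min_gentrain or call_rate < thresholds.min_call_rate:
        klass = "other_fail"
    else:
        classes_present = {c for c in calls if c in ("AA", "AB", "BB")}
        if len(classes_present) == 1 and classes_present <= {"AA", "BB"}:
            klass = "monomorphic"
        elif Fe is not None and Fe >= thresholds.min_fe:
            klass = "paralogous"
        else:
            klass = "valid"
    return MarkerQC(
        marker_id="", call_rate=call_rate, p=p, Ho=Ho, He=He, Fe=Fe,
        klass=klass, gentrain_score=gentrain,
    )


def classify_matrix(
    matrix: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> list[MarkerQC]:
    """Classify every marker of a genotype matrix."""
    results = []
    calls = matrix.calls
    for marker_id in calls.index:
        row = calls.loc[marker_id]
        meta = matrix.markers.loc[marker_id]
        qc = classify_marker(
            row.tolist(), float(meta["gentrain_score"]), thresholds
        )
        qc.marker_id = str(marker_id)
        qc.source = str(meta["source"]) if "source" in meta else None
        results.append(qc)
    return results


def replicate_concordance(matrix: GenotypeMatrix) -> tuple[float, int]:
    """Genotype concordance between replicated samples, as a percentage.

    Over all (marker, replicate-pair) cells where both members are called,
    returns (100 x fraction identical, number of cells compared).
    """
    if not matrix.replicate_pairs:
        raise DomainError("no replicate pairs defined in the genotype matrix")
    compared = 0
    concordant = 0
    for a, b in matrix.replicate_pairs:
        ca = matrix.calls[a].to_numpy()
        cb = matrix.calls[b].to_numpy()
        both = (ca != "NC") & (cb != "NC")
        compared += int(both.sum())
        concordant += int((ca[both] == cb[both]).sum())
    if compared == 0:
        raise DomainError("no replicate cells with both members called")
    return 100.0 * concordant / compared, compared


def success_rate(n_valid: int, n_manufactured: int) -> float:
    """Percent of manufactured markers yielding valid assays."""
    if n_manufactured <= 0:
        raise DomainError("n_manufactured must be positive")
    return 100.0 * n_valid / n_manufactured


@dataclass
class TprReport:
    """Per-source and total class tallies plus success rates (percent)."""

    rows: pd.DataFrame  # index: source + "total"; columns: counts + success_rate

    def to_dict(self) -> dict:
        return self.rows.to_dict(orient="index")


def tpr_report(markers: Iterable[MarkerQC]) -> TprReport:
    """Tabulate QC classes by SNP source with a grand-total row.

    Row invariant: valid + monomorphic + paralogous + other_fail =
    manufactured, and success_rate = 100 x valid / manufactured.
    """
    markers = list(markers)
    if any(m.source is None for m in markers):
        raise InputValidationError("every marker needs a source label for the report")
    df = pd.DataFrame(
        {"source": [m.source for m in markers], "klass": [m.klass for m in markers]}
    )
    counts = (
        df.groupby("source")["klass"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["valid", "monomorphic", "paralogous", "other_fail"], fill_value=0)
    )
    counts.loc["total"] = counts.sum()
    counts["n_manufactured"] = counts.sum(axis=1)
    counts["n_failed"] = (
        counts["monomorphic"] + counts["paralogous"] + counts["other_fail"]
    )
    counts["success_rate"] = 100.0 * counts["valid"] / counts["n_manufactured"]
    return TprReport(rows=counts)
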