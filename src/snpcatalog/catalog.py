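"""Consensus SNP catalog construction.

Two independent variant callers are run on the same reference-guided
alignments; only sites called by both are considered further, and those must
then clear a conjunction of per-site quality criteria before entering the
high-confidence catalog.  One caller (the Platypus-style one, caller ``A``)
is the annotation-of-record: its quality fields, read counts and therefore
depth/MAF are the ones evaluated and reported, while the second caller
contributes site confirmation only, since it does not emit these fields.

Quality criteria (all must hold):

=========  =====================================================  =========
field      meaning                                                 threshold
=========  =====================================================  =========
MQ         root-mean-square mapping quality                        >= 20
MMLQ       median minimum base quality around the variant          >= 10
QD         quality by depth                                        >= 10
PP         posterior probability                                   >= 20
SbPval     binomial strand-bias p-value                            >= 0.01
HapScore   haplotype score                                         >= 15
MGOF       goodness-of-fit statistic                               >= 20 (*)
SC         sequence-context score                                  >= 0.95
alt reads  support for the alternative allele (non-singleton)      >= 2
alleles    exactly one alternative allele (bi-allelic site)
=========  =====================================================  =========

(*) The MGOF criterion is applied as a lower bound, matching its published
form; because a goodness-of-fit cap would normally be an upper bound, a
configuration switch (``mgof_inverted``) flips the comparison for
sensitivity analyses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import CoordinateError, DomainError, InputValidationError

__all__ = [
    "ContigRecord",
    "CallerVariant",
    "MatchedPair",
    "FilterThresholds",
    "ConsensusSNP",
    "CatalogSummary",
    "intersect_callsets",
    "apply_quality_filters",
    "extract_flanks",
    "build_consensus_snp",
    "summarize_catalog",
    "summarize_catalog_counts",
    "union_size",
]

#: Names of the audited filters, in report order.
FILTER_NAMES = (
    "MQ",
    "MMLQ",
    "QD",
    "PP",
    "SbPval",
    "HapScore",
    "MGOF",
    "SC",
    "min_alt_reads",
    "biallelic",
)


@dataclass(frozen=True)
class ContigRecord:
    """A reference contig: sequence plus its mean sequencing depth."""

    contig_id: str
    sequence: str
    mean_depth: float

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CallerVariant:
    """A single caller's variant record with its quality annotations.

    Quality fields may be ``None`` for the confirmation-only caller; the
    filter stage raises if the annotation-of-record is missing one.
    """

    caller_id: str  # "A" (annotation-of-record) or "B"
    contig_id: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    MQ: float | None = None
    MMLQ: float | None = None
    QD: float | None = None
    PP: float | None = None
    SbPval: float | None = None
    HapScore: float | None = None
    MGOF: float | None = None
    SC: float | None = None
    ref_reads: int = 0
    alt_reads: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DomainError(f"pos must be >= 1, got {self.pos}")
        if self.SbPval is not None and not 0.0 <= self.SbPval <= 1.0:
            raise DomainError(f"SbPval must lie in [0,1], got {self.SbPval}")
        if self.SC is not None and not 0.0 <= self.SC <= 1.0:
            raise DomainError(f"SC must lie in [0,1], got {self.SC}")
        if self.ref_reads < 0 or any(a < 0 for a in self.alt_reads):
            raise DomainError("read counts must be non-negative")

    @property
    def site(self) -> tuple[str, int]:
        return (self.contig_id, self.pos)

    def normalized_alleles(self) -> tuple[str, tuple[str, ...]]:
        return self.ref.upper(), tuple(a.upper() for a in self.alts)


@dataclass(frozen=True)
class MatchedPair:
    """A site reported by both callers with identical normalized alleles."""

    a: CallerVariant
    b: CallerVariant


@dataclass(frozen=True)
class FilterThresholds:
    """The in-house high-confidence criteria (defaults as published)."""

    min_mq: float = 20.0
    min_mmlq: float = 10.0
    min_qd: float = 10.0
    min_pp: float = 20.0
    min_sbpval: float = 0.01
    min_hapscore: float = 15.0
    mgof_threshold: float = 20.0
    mgof_inverted: bool = False  # True -> MGOF <= threshold
    min_sc: float = 0.95
    min_alt_reads: int = 2


@dataclass(frozen=True)
class ConsensusSNP:
    """A bi-allelic, filter-passing catalog SNP with its flanking sequence."""

    contig_id: str
    pos: int
    ref: str
    alt: str
    depth: int
    maf: float
    flank_up: str = ""
    flank_down: str = ""
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise DomainError(f"MAF must lie in [0, 0.5], got {self.maf}")
        if len(self.flank_up) > 100 or len(self.flank_down) > 100:
            raise DomainError("flanks must not exceed 100 bp")


@dataclass
class CatalogSummary:
    n_snps: int
    n_snped_genes: int
    n_unsnped_genes: int
    snps_per_snped_gene: float
    snps_per_gene_all: float
    abundance_per_100: float  # SNPs per 100 bp over the SNPed genes
    sites_per_snp: int | None  # round(100 / abundance), None when undefined


def _dedupe_check(variants: Sequence[CallerVariant], label: str) -> dict:
    seen: dict[tuple[str, int], CallerVariant] = {}
    dupes = []
    for v in variants:
        if v.site in seen:
            dupes.append(v.site)
        else:
            seen[v.site] = v
    if dupes:
        raise InputValidationError(
            f"duplicate (contig, pos) keys in set {label}: {sorted(set(dupes))[:10]}"
        )
    return seen


def union_size(n_a: int, n_b: int, n_common: int) -> int:
    """|A ∪ B| = |A| + |B| − |A ∩ B| for two internally deduplicated call sets."""
    if min(n_a, n_b, n_common) < 0 or n_common > min(n_a, n_b):
        raise DomainError("inconsistent set sizes for union computation")
    return n_a + n_b - n_common


def intersect_callsets(
    set_a: Sequence[CallerVariant], set_b: Sequence[CallerVariant]
) -> tuple[list[MatchedPair], int]:
    """Match the two call sets on site and alleles.

    A site is common when both callers report the same (contig, position)
    with an identical reference allele and an identical normalized
    alternative-allele tuple.  Allele arity is not restricted here — the
    bi-allelic rule is enforced (and audited) by the filter cascade.
    Returns the matched pairs and the union size |A| + |B| − |common|.
    """
    index_a = _dedupe_check(set_a, "A")
    index_b = _dedupe_check(set_b, "B")
    common: list[MatchedPair] = []
    for site, va in index_a.items():
        vb = index_b.get(site)
        if vb is None:
            continue
        if va.normalized_alleles() == vb.normalized_alleles():
            common.append(MatchedPair(a=va, b=vb))
    return common, union_size(len(index_a), len(index_b), len(common))


def failed_filters(
    variant: CallerVariant, thresholds: FilterThresholds = FilterThresholds()
) -> list[str]:
    """Names of the criteria this annotation-of-record variant violates.

    Raises :class:`InputValidationError` when a required annotation is
    missing, naming the site and field.
    """
    checks: list[tuple[str, float | None, bool]] = []
    t = thresholds
    for name, value, ok in (
        ("MQ", variant.MQ, (variant.MQ or 0) >= t.min_mq),
        ("MMLQ", variant.MMLQ, (variant.MMLQ or 0) >= t.min_mmlq),
        ("QD", variant.QD, (variant.QD or 0) >= t.min_qd),
        ("PP", variant.PP, (variant.PP or 0) >= t.min_pp),
        ("SbPval", variant.SbPval, (variant.SbPval or 0) >= t.min_sbpval),
        ("HapScore", variant.HapScore, (variant.HapScore or 0) >= t.min_hapscore),
        (
            "MGOF",
            variant.MGOF,
            ((variant.MGOF or 0) <= t.mgof_threshold)
            if t.mgof_inverted
            else ((variant.MGOF or 0) >= t.mgof_threshold),
        ),
        ("SC", variant.SC, (variant.SC or 0) >= t.min_sc),
    ):
        if value is None:
            raise InputValidationError(
                f"variant {variant.contig_id}:{variant.pos} lacks annotation {name}"
            )
        checks.append((name, value, ok))
    failed = [name for name, _, ok in checks if not ok]
    if sum(variant.alt_reads) < t.min_alt_reads:
        failed.append("min_alt_reads")
    if len(variant.alts) != 1:
        failed.append("biallelic")
    return failed


def apply_quality_filters(
    common: Sequence[MatchedPair], thresholds: FilterThresholds = FilterThresholds()
) -> tuple[list[MatchedPair], Counter]:
    """Evaluate the conjunction of quality criteria on each matched site.

    Criteria are read from the annotation-of-record (caller A).  The audit
    counter tallies every violated criterion of every rejected site, so its
    total can exceed the number of rejections.
    """
    passing: list[MatchedPair] = []
    audit: Counter = Counter({name: 0 for name in FILTER_NAMES})
    for pair in common:
        failed = failed_filters(pair.a, thresholds)
        if failed:
            audit.update(failed)
        else:
            passing.append(pair)
    return passing, audit


def extract_flanks(
    pos: int, sequence: str | ContigRecord, width: int = 100
) -> tuple[str, str]:
    """Sequence up to ``width`` bp on each side of a 1-based position.

    Flanks are truncated at the contig ends; the variant base itself is
    excluded from both.
    """
    if isinstance(sequence, ContigRecord):
        sequence = sequence.sequence
    L = len(sequence)
    if not 1 <= pos <= L:
        raise CoordinateError(f"pos {pos} outside contig of length {L}")
    up = sequence[max(0, pos - 1 - width) : pos - 1]
    down = sequence[pos : pos + width]
    return up, down


def build_consensus_snp(
    pair: MatchedPair,
    contig_sequence: str | None = None,
    gene_id: str | None = None,
    flank_width: int = 100,
) -> ConsensusSNP:
    """Materialize a catalog row from a passing matched pair.

    Depth and MAF come from the annotation-of-record's read counts:
    depth = ref + alt reads, MAF = min(f, 1-f) with f the alt-read fraction.
    """
    v = pair.a
    if len(v.alts) != 1:
        raise DomainError(
            f"consensus SNP at {v.contig_id}:{v.pos} must be bi-allelic"
        )
    alt_reads = v.alt_reads[0] if v.alt_reads else 0
    depth = v.ref_reads + alt_reads
    f = alt_reads / depth if depth > 0 else 0.0
    maf = min(f, 1.0 - f)
    flank_up = flank_down = ""
    if contig_sequence is not None:
        flank_up, flank_down = extract_flanks(v.pos, contig_sequence, flank_width)
    ref, alts = v.normalized_alleles()
    return ConsensusSNP(
        contig_id=v.contig_id,
        pos=v.pos,
        ref=ref,
        alt=alts[0],
        depth=depth,
        maf=maf,
        flank_up=flank_up,
        flank_down=flank_down,
        gene_id=gene_id,
    )


def summarize_catalog(
    snps: Sequence[ConsensusSNP],
    paired_genes: set[str],
    gene_lengths: Mapping[str, int],
) -> CatalogSummary:
    """Catalog-level statistics over the paired gene universe.

    ``abundance_per_100`` is SNPs per 100 bp of summed SNPed-gene length;
    ``sites_per_snp`` its rounded reciprocal on the same gene set.
    """
    snped_genes = {s.gene_id for s in snps if s.gene_id is not None}
    if not snped_genes <= paired_genes:
        raise InputValidationError(
            f"SNPs reference genes outside the paired set: "
            f"{sorted(snped_genes - paired_genes)[:5]}"
        )
    n_snps = len(snps)
    n_snped = len(snped_genes)
    n_unsnped = len(paired_genes) - n_snped
    snped_len = sum(gene_lengths[g] for g in snped_genes)
    per_snped = n_snps / n_snped if n_snped else float("nan")
    per_all = n_snps / len(paired_genes) if paired_genes else float("nan")
    if snped_len > 0:
        abundance = 100.0 * n_snps / snped_len
        sites = round(100.0 / abundance) if abundance > 0 else None
    else:
        abundance, sites = float("nan"), None
    return CatalogSummary(
        n_snps=n_snps,
        n_snped_genes=n_snped,
        n_unsnped_genes=n_unsnped,
        snps_per_snped_gene=per_snped,
        snps_per_gene_all=per_all,
        abundance_per_100=abundance,
        sites_per_snp=sites,
    )


def summarize_catalog_counts(
    n_snps: int,
    n_snped_genes: int,
    n_paired_genes: int,
    abundance_per_100: float | None = None,
) -> CatalogSummary:
    """Catalog accounting from bare tallies.

    The same ratios :func:`summarize_catalog` derives, for when only the
    counts of a completed catalog are available; ``abundance_per_100`` may be
    supplied directly when the underlying gene lengths are not."""
    if n_snped_genes > n_paired_genes or min(n_snps, n_snped_genes) < 0:
        raise DomainError("inconsistent catalog counts")
    per_snped = n_snps / n_snped_genes if n_snped_genes else float("nan")
    per_all = n_snps / n_paired_genes if n_paired_genes else float("nan")
    abundance = float("nan") if abundance_per_100 is None else abundance_per_100
    sites = (
        round(100.0 / abundance)
        if abundance_per_100 is not None and abundance > 0
        else None
    )
    return CatalogSummary(
        n_snps=n_snps,
        n_snped_genes=n_snped_genes,
        n_unsnped_genes=n_paired_genes - n_snped_genes,
        snps_per_snped_gene=per_snped,
        snps_per_gene_all=per_all,
        abundance_per_100=abundance,
        sites_per_snp=sites,
    )
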