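"""Synthetic study generator.

Every input the pipeline consumes can be generated here with known ground
truth: reference contigs with a contig-to-target hit table, two caller call
sets with a controlled intersection and planted quality-filter violations, a
genotype matrix with markers of known QC class, and functional annotations
over a small ontology with designated enriched categories.  The generator
emulates, at reduced scale, a pooled exome-capture experiment: two DNA pools
sequenced and called by two independent callers, followed by array
genotyping of a breeding population.

Defaults mirror the study design the pipeline was built for — a caller-set
Jaccard of 0.285 and a 9 % filter-failure fraction among intersection sites,
array marker classes of roughly 9 % paralogous, 5.5 % monomorphic and 1.3 %
other failures, per-bp SNP rate of 0.003, and a [25, 800] usable coverage
window — so that a default synthetic run exercises every decision the real
pipeline had to make.

All randomness flows through ``numpy``'s ``default_rng`` seeded per
operation from ``SynthConfig.rng_seed``; identical configs therefore yield
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import ContigAbundance, contig_abundance, harmonic_number
from .catalog import CallerVariant, ContigRecord
from .enrichment import AnnotationTable
from .errors import ConfigError
from .genotyping_qc import GenotypeMatrix
from .pairing import TargetHit

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SynthBundle",
    "generate_reference",
    "generate_caller_sets",
    "generate_genotype_matrix",
    "generate_annotations",
    "sample_functionality_scores",
    "generate_depth_coupled_contigs",
    "generate_null_annotations",
    "simulate_study",
]

_BASES = np.array(list("ACGT"))

#: Planted filter violations cycle through these names so every criterion
#: gets attributable failures.
_PLANTABLE_FILTERS = (
    "MQ", "MMLQ", "QD", "PP", "SbPval", "HapScore", "MGOF", "SC",
    "min_alt_reads", "biallelic",
)

# distinct per-operation rng streams derived from the config seed
_STREAM = {"reference": 1, "callers": 2, "genotypes": 3, "annotations": 4}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic study; defaults emulate the real design."""

    n_genes: int = 200                     # targeted genes
    n_contigs: int = 300                   # assembled contigs
    contig_len_range: tuple[int, int] = (400, 2000)   # bp; spans the 500 bp gate
    mean_depth_range: tuple[float, float] = (10.0, 900.0)  # spans [25, 800]
    true_snp_rate: float = 0.003           # SNPs per bp
    caller_jaccard: float = 0.285          # |A∩B| / |A∪B| target
    filter_fail_fraction: float = 0.09     # of intersection sites
    n_markers: int = 1000
    n_samples: int = 100
    paralog_fraction: float = 0.09
    monomorph_fraction: float = 0.055
    other_fail_fraction: float = 0.013
    genotype_error_rate: float = 0.0
    rng_seed: int = 0
    # annotation / enrichment plumbing
    n_families: int = 30
    orphan_rate: float = 0.10
    conifer_rate: float = 0.06
    enriched_family_size: int = 12
    enrichment_multiplier: float = 6.0     # SNP-rate boost of designated genes

    def __post_init__(self) -> None:
        for name in (
            "caller_jaccard", "filter_fail_fraction", "paralog_fraction",
            "monomorph_fraction", "other_fail_fraction", "genotype_error_rate",
            "orphan_rate", "conifer_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.contig_len_range[0] <= 200:
            raise ConfigError(
                f"contig_len_range minimum must exceed 200 bp, got "
                f"{self.contig_len_range[0]}"
            )
        if self.contig_len_range[0] > self.contig_len_range[1]:
            raise ConfigError("contig_len_range must be (min, max)")
        if self.n_samples < 4:
            raise ConfigError(f"n_samples must be >= 4, got {self.n_samples}")
        for name in ("n_genes", "n_contigs", "n_markers"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.paralog_fraction + self.monomorph_fraction + self.other_fail_fraction > 1:
            raise ConfigError("marker class fractions sum to more than 1")
        if self.true_snp_rate < 0:
            raise ConfigError("true_snp_rate must be >= 0")


@dataclass
class GroundTruth:
    """Construction-time labels for every emitted variant, marker, category.

    ``variants`` is indexed by (contig_id, pos) with columns in_both_callers,
    passes_quality, is_singleton, is_biallelic, failed_filter; ``markers`` by
    marker id with column true_class; ``categories`` by category id with
    columns kind and enriched_in_top_decile.
    """

    variants: pd.DataFrame | None = None
    markers: pd.DataFrame | None = None
    categories: pd.DataFrame | None = None


@dataclass
class SynthBundle:
    """Everything one synthetic study produces, inputs plus ground truth."""

    config: SynthConfig
    contigs: list[ContigRecord]
    hits: list[TargetHit]
    gene_map: pd.DataFrame
    set_a: list[CallerVariant]
    set_b: list[CallerVariant]
    matrix: GenotypeMatrix
    annotations: AnnotationTable
    go_edges: list[tuple[str, str]]
    truth: GroundTruth

    @property
    def contig_by_id(self) -> dict[str, ContigRecord]:
        return {c.contig_id: c for c in self.contigs}


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], config.rng_seed])


def _gene_ids(config: SynthConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(config.n_genes)]


def generate_reference(
    config: SynthConfig,
) -> tuple[list[ContigRecord], list[TargetHit], pd.DataFrame]:
    """Reference contigs, their target-gene hit table, and the truth map.

    Each contig carries one hit against its assigned gene.  Identities,
    e-values and coverages are drawn so that most rows clear the retention
    thresholds while a known minority fails each criterion, and contig
    lengths straddle the 500 bp gate — the pairing filter is exercised on
    both sides of every boundary.
    """
    rng = _rng(config, "reference")
    genes = _gene_ids(config)
    lo, hi = config.contig_len_range
    dlo, dhi = config.mean_depth_range
    contigs: list[ContigRecord] = []
    hits: list[TargetHit] = []
    rows = []
    for i in range(config.n_contigs):
        contig_id = f"C{i:05d}"
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_BASES, size=length))
        depth = float(rng.uniform(dlo, dhi))
        gene = genes[int(rng.integers(0, config.n_genes))]
        # ~85 % of identities above the 95 % gate, the rest just below
        if rng.uniform() < 0.85:
            identity = float(rng.uniform(95.0, 100.0))
        else:
            identity = float(rng.uniform(90.0, 94.99))
        # ~95 % of e-values clear the 1e-5 gate
        if rng.uniform() < 0.95:
            evalue = float(10.0 ** rng.uniform(-30.0, -6.0))
        else:
            evalue = float(10.0 ** rng.uniform(-4.9, -3.0))
        contigs.append(ContigRecord(contig_id, seq, depth))
        hits.append(
            TargetHit(
                contig_id=contig_id,
                gene_id=gene,
                identity=identity,
                evalue=evalue,
                mean_coverage=depth,
                contig_length=length,
            )
        )
        rows.append({"contig_id": contig_id, "gene_id": gene})
    gene_map = pd.DataFrame(rows).set_index("contig_id")
    return contigs, hits, gene_map


def _passing_annotations(rng: np.random.Generator) -> dict:
    """Quality fields drawn comfortably inside every filter bound."""
    return dict(
        MQ=float(rng.uniform(25, 60)),
        MMLQ=float(rng.uniform(15, 40)),
        QD=float(rng.uniform(12, 40)),
        PP=float(rng.uniform(30, 100)),
        SbPval=float(rng.uniform(0.05, 1.0)),
        HapScore=float(rng.uniform(16, 30)),
        MGOF=float(rng.uniform(22, 60)),
        SC=float(rng.uniform(0.955, 1.0)),
    )


def _violate(fields: dict, name: str, rng: np.random.Generator) -> None:
    """Overwrite exactly one quality field with a value failing its bound."""
    draw = {
        "MQ": lambda: rng.uniform(0, 19.5),
        "MMLQ": lambda: rng.uniform(0, 9.5),
        "QD": lambda: rng.uniform(0, 9.5),
        "PP": lambda: rng.uniform(0, 19.5),
        "SbPval": lambda: rng.uniform(0, 0.009),
        "HapScore": lambda: rng.uniform(0, 14.5),
        "MGOF": lambda: rng.uniform(0, 19.5),
        "SC": lambda: rng.uniform(0.5, 0.9499),
    }[name]
    fields[name] = float(draw())


def _read_counts(
    depth: float, rng: np.random.Generator, singleton: bool = False
) -> tuple[int, int]:
    """(ref_reads, alt_reads) for one site around the contig's mean depth."""
    total = max(4, int(round(rng.normal(depth, 0.1 * depth))))
    if singleton:
        return total - 1, 1
    alt = int(round(total * rng.uniform(0.1, 0.9)))
    alt = min(max(alt, 2), total - 1)
    return total - alt, alt


def generate_caller_sets(
    contigs: Sequence[ContigRecord],
    config: SynthConfig,
    rate_multipliers: Mapping[str, float] | None = None,
    gene_map: pd.DataFrame | None = None,
) -> tuple[list[CallerVariant], list[CallerVariant], GroundTruth]:
    """Two caller call sets over the contigs, with labelled ground truth.

    True variant sites are placed uniformly at ``true_snp_rate`` per bp
    (optionally scaled per gene through ``rate_multipliers`` and the
    contig-to-gene ``gene_map``).  Each site lands in both call sets with
    probability ``caller_jaccard`` and in exactly one otherwise, which makes
    the realized Jaccard of the two site lists concentrate on the configured
    value.  A ``filter_fail_fraction`` of intersection sites is given exactly
    one planted violation, cycling through all ten audited criteria —
    including singletons (one alternative read) and tri-allelic sites.
    """
    if not contigs:
        raise ConfigError("generate_caller_sets requires a non-empty contig list")
    rng = _rng(config, "callers")
    set_a: list[CallerVariant] = []
    set_b: list[CallerVariant] = []
    truth_rows = []
    fail_cycle = 0
    for contig in contigs:
        mult = 1.0
        if rate_multipliers is not None and gene_map is not None:
            if contig.contig_id in gene_map.index:
                gene = gene_map.loc[contig.contig_id, "gene_id"]
                mult = float(rate_multipliers.get(gene, 1.0))
        n_sites = rng.poisson(config.true_snp_rate * mult * contig.length)
        n_sites = min(n_sites, contig.length)
        if n_sites == 0:
            continue
        positions = np.sort(
            rng.choice(contig.length, size=n_sites, replace=False) + 1
        )
        for pos in positions:
            ref = contig.sequence[pos - 1]
            alt = str(rng.choice(_BASES[_BASES != ref]))
            u = rng.uniform()
            in_both = u < config.caller_jaccard
            in_a = in_both or u < config.caller_jaccard + (1 - config.caller_jaccard) / 2
            fields = _passing_annotations(rng)
            alts: tuple[str, ...] = (alt,)
            singleton = False
            failed = ""
            if in_both and rng.uniform() < config.filter_fail_fraction:
                failed = _PLANTABLE_FILTERS[fail_cycle % len(_PLANTABLE_FILTERS)]
                fail_cycle += 1
                if failed == "min_alt_reads":
                    singleton = True
                elif failed == "biallelic":
                    third = str(rng.choice(_BASES[(_BASES != ref) & (_BASES != alt)]))
                    alts = (alt, third)
                else:
                    _violate(fields, failed, rng)
            ref_reads, alt_reads = _read_counts(contig.mean_depth, rng, singleton)
            alt_read_tuple = (
                (alt_reads,) if len(alts) == 1
                else (max(1, alt_reads - 1), 1)
            )
            if in_a:
                set_a.append(
                    CallerVariant(
                        caller_id="A", contig_id=contig.contig_id, pos=int(pos),
                        ref=ref, alts=alts, ref_reads=ref_reads,
                        alt_reads=alt_read_tuple, **fields,
                    )
                )
            if in_both or not in_a:
                set_b.append(
                    CallerVariant(
                        caller_id="B", contig_id=contig.contig_id, pos=int(pos),
                        ref=ref, alts=alts, ref_reads=ref_reads,
                        alt_reads=alt_read_tuple, **fields,
                    )
                )
            truth_rows.append(
                {
                    "contig_id": contig.contig_id,
                    "pos": int(pos),
                    "in_both_callers": bool(in_both),
                    "passes_quality": bool(in_both and not failed),
                    "is_singleton": singleton,
                    "is_biallelic": len(alts) == 1,
                    "failed_filter": failed,
                }
            )
    variants = pd.DataFrame(truth_rows)
    if not variants.empty:
        variants = variants.set_index(["contig_id", "pos"])
    return set_a, set_b, GroundTruth(variants=variants)


def _hwe_calls(
    p: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    probs = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    return rng.choice(np.array(["AA", "AB", "BB"]), size=n, p=probs / probs.sum())


def _is_single_homozygous(calls: np.ndarray) -> bool:
    present = set(calls[calls != "NC"])
    return len(present) == 1 and present <= {"AA", "BB"}


def _het_excess(calls: np.ndarray) -> float:
    called = calls[calls != "NC"]
    n = len(called)
    if n == 0:
        return 0.0
    n_aa = int(np.sum(called == "AA"))
    n_ab = int(np.sum(called == "AB"))
    p = (2 * n_aa + n_ab) / (2 * n)
    ho = n_ab / n
    he = 2 * p * (1 - p)
    if he >= 1.0 or ho <= he:
        return 0.0
    return (ho - he) / (1 - he)


def generate_genotype_matrix(
    config: SynthConfig,
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Genotype matrix with markers of known QC class.

    Valid markers segregate at Hardy-Weinberg proportions with a minor-allele
    frequency drawn uniformly in [0.05, 0.5] (a breeding-population panel in
    which rare alleles are under-represented); paralogous markers are
    near-obligate heterozygotes (P(AB) = 0.95); monomorphic markers show one
    homozygous class; other failures split between a sub-threshold
    clustering score and a sub-80 % call rate.  Two replicate sample pairs
    are appended for concordance testing, and ``genotype_error_rate``
    miscalls each called cell independently.
    """
    rng = _rng(config, "genotypes")
    n_m, n_s = config.n_markers, config.n_samples
    n_par = int(round(config.paralog_fraction * n_m))
    n_mono = int(round(config.monomorph_fraction * n_m))
    n_other = int(round(config.other_fail_fraction * n_m))
    classes = np.array(
        ["paralogous"] * n_par
        + ["monomorphic"] * n_mono
        + ["other_fail"] * n_other
        + ["valid"] * (n_m - n_par - n_mono - n_other)
    )
    rng.shuffle(classes)
    # controls mirror the predicted markers at a small fixed fraction
    sources = np.where(rng.uniform(size=n_m) < 0.02, "control", "predicted")

    samples = [f"S{i:04d}" for i in range(n_s)]
    rep_pairs = [(samples[0], "R0000"), (samples[1], "R0001")]
    calls = np.empty((n_m, n_s), dtype=object)
    gentrain = np.empty(n_m)
    for i, klass in enumerate(classes):
        gentrain[i] = float(rng.uniform(0.4, 0.99))
        if klass == "valid":
            maf = float(rng.uniform(0.05, 0.5))
            p = maf if rng.uniform() < 0.5 else 1 - maf
            for _ in range(100):
                row = _hwe_calls(p, n_s, rng)
                if not _is_single_homozygous(row) and _het_excess(row) < 0.8:
                    break
            calls[i] = row
        elif klass == "paralogous":
            for _ in range(100):
                row = rng.choice(
                    np.array(["AB", "AA", "BB"]), size=n_s, p=[0.95, 0.025, 0.025]
                )
                if _het_excess(row) >= 0.8:
                    break
            calls[i] = row
        elif klass == "monomorphic":
            calls[i] = np.full(n_s, "AA" if rng.uniform() < 0.5 else "BB")
        else:  # other_fail
            maf = float(rng.uniform(0.05, 0.5))
            row = _hwe_calls(maf, n_s, rng)
            if rng.uniform() < 0.5:
                gentrain[i] = float(rng.uniform(0.0, 0.12))
            else:
                n_nc = max(1, int(math.ceil(0.3 * n_s)))
                nc_idx = rng.choice(n_s, size=n_nc, replace=False)
                row = row.copy()
                row[nc_idx] = "NC"
            calls[i] = row

    df = pd.DataFrame(
        calls, index=[f"M{i:05d}" for i in range(n_m)], columns=samples
    )
    # replicate columns duplicate the first two samples
    for original, rep in rep_pairs:
        df[rep] = df[original]

    if config.genotype_error_rate > 0:
        states = np.array(["AA", "AB", "BB"])
        arr = df.to_numpy()
        err_mask = (rng.uniform(size=arr.shape) < config.genotype_error_rate) & (
            arr != "NC"
        )
        for r, c in zip(*np.nonzero(err_mask)):
            arr[r, c] = str(rng.choice(states[states != arr[r, c]]))
        df = pd.DataFrame(arr, index=df.index, columns=df.columns)

    markers = pd.DataFrame(
        {"gentrain_score": gentrain, "source": sources}, index=df.index
    )
    matrix = GenotypeMatrix(calls=df, markers=markers, replicate_pairs=rep_pairs)
    truth = GroundTruth(
        markers=pd.DataFrame({"true_class": classes}, index=df.index)
    )
    return matrix, truth


def _build_dag() -> list[tuple[str, str]]:
    """A fixed four-level ontology (root, 4 branches, 12 mid, 24 leaf terms)."""
    edges: list[tuple[str, str]] = []
    for b in range(4):
        edges.append((f"T1:{b}", "T0:root"))
        for m in range(3):
            mid = f"T2:{b}.{m}"
            edges.append((mid, f"T1:{b}"))
            for l in range(2):
                edges.append((f"T3:{b}.{m}.{l}", mid))
    # a couple of multi-parent terms, as in real ontologies
    edges.append(("T3:0.0.0", "T2:1.0"))
    edges.append(("T2:2.1", "T1:3"))
    return edges


DESIGNATED_FAMILY = "FAM_ENRICHED"
DESIGNATED_TERM = "T3:0.1.0"


def generate_annotations(
    config: SynthConfig,
) -> tuple[AnnotationTable, list[tuple[str, str]], GroundTruth, dict[str, float]]:
    """Gene annotations, the ontology edge list, and enrichment ground truth.

    One designated family and one designated leaf term share a block of
    ``enriched_family_size`` genes whose SNP rate is boosted by
    ``enrichment_multiplier``; running the full pipeline therefore lands
    those genes in the top abundance decile and makes both categories
    detectably enriched.  The returned multiplier map feeds
    :func:`generate_caller_sets`.
    """
    rng = _rng(config, "annotations")
    genes = _gene_ids(config)
    edges = _build_dag()
    terms = sorted({c for c, _ in edges} | {p for _, p in edges})
    leafish = [t for t in terms if t.startswith(("T2", "T3"))]

    go: dict[str, set[str]] = {}
    for g in genes:
        if rng.uniform() < 0.7:
            k = int(rng.integers(1, 4))
            go[g] = set(rng.choice(leafish, size=k, replace=False))

    enriched_genes = list(rng.choice(genes, size=config.enriched_family_size, replace=False))
    family: dict[str, str] = {}
    orphan: set[str] = set()
    conifer: set[str] = set()
    for g in genes:
        if g in enriched_genes:
            family[g] = DESIGNATED_FAMILY
        elif rng.uniform() < config.orphan_rate:
            orphan.add(g)
        else:
            family[g] = f"FAM{int(rng.integers(0, config.n_families)):03d}"
        if rng.uniform() < config.conifer_rate:
            conifer.add(g)
    for g in enriched_genes:
        go.setdefault(g, set()).add(DESIGNATED_TERM)

    annotations = AnnotationTable(
        go=go, family=family, orphan=orphan, conifer_specific=conifer
    )
    multipliers = {g: config.enrichment_multiplier for g in enriched_genes}
    categories = pd.DataFrame(
        [
            {"category": DESIGNATED_FAMILY, "kind": "family",
             "enriched_in_top_decile": True},
            {"category": DESIGNATED_TERM, "kind": "go_term",
             "enriched_in_top_decile": True},
        ]
    ).set_index("category")
    return annotations, edges, GroundTruth(categories=categories), multipliers


def sample_functionality_scores(
    snp_keys: Sequence[tuple[str, int]], seed: int
) -> dict[tuple[str, int], float]:
    """Assay functionality scores for catalog SNPs.

    Drawn from a Beta(5, 2) distribution (mean ~0.71), which straddles the
    0.60 design threshold so that some candidates fail on score alone.
    Scores are an opaque input to candidate selection, not computed from
    sequence.
    """
    rng = np.random.default_rng([7, seed])
    scores = rng.beta(5.0, 2.0, size=len(snp_keys))
    return {key: float(s) for key, s in zip(snp_keys, scores)}


def generate_depth_coupled_contigs(
    n_contigs: int,
    seed: int,
    *,
    theta: float = 0.002,
    len_range: tuple[int, int] = (500, 2000),
    depth_range: tuple[float, float] = (5.0, 300.0),
) -> list[ContigAbundance]:
    """Contigs whose observed SNP yield is coupled to sequencing depth.

    The expected number of segregating sites per contig follows the
    Watterson-style expectation ``theta * L * H(floor(D) - 1)``: deeper
    contigs mechanically yield more SNPs even though the underlying
    polymorphism rate ``theta`` is constant.  Raw per-bp SNP density should
    therefore correlate with depth while the corrected beta should not.
    """
    rng = np.random.default_rng([5, seed])
    out = []
    for i in range(n_contigs):
        L = int(rng.integers(len_range[0], len_range[1] + 1))
        D = float(rng.uniform(depth_range[0], depth_range[1]))
        H = harmonic_number(math.floor(D) - 1)
        S = int(rng.poisson(theta * L * H))
        out.append(contig_abundance(f"C{i:05d}", S, L, D))
    return out


def generate_null_annotations(
    n_terms: int,
    universe_size: int,
    seed: int,
    *,
    top_fraction: float = 0.10,
    term_size_range: tuple[int, int] = (50, 400),
) -> tuple[dict[str, set[str]], set[str], set[str]]:
    """A null enrichment instance: random terms, random top set, no signal.

    Term sizes are drawn uniformly in ``term_size_range`` — tables large
    enough that the discrete Fisher test attains a size near its nominal
    level, which is what calibration checks presume.  Returns (gene -> term
    annotations, top set, universe).
    """
    rng = np.random.default_rng([6, seed])
    universe = {f"G{i:05d}" for i in range(universe_size)}
    genes = sorted(universe)
    top = set(rng.choice(genes, size=int(top_fraction * universe_size), replace=False))
    annotations: dict[str, set[str]] = {g: set() for g in genes}
    for t in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        members = rng.choice(genes, size=size, replace=False)
        term = f"NT:{t:05d}"
        for g in members:
            annotations[g].add(term)
    return annotations, top, universe


def simulate_study(config: SynthConfig) -> SynthBundle:
    """Generate every pipeline input for one synthetic study.

    Annotations come first (they define which genes carry boosted SNP
    rates), then the reference, the caller sets and the genotype matrix.
    Ground-truth frames from all generators are merged into one record.
    """
    annotations, edges, truth_cat, multipliers = generate_annotations(config)
    contigs, hits, gene_map = generate_reference(config)
    set_a, set_b, truth_var = generate_caller_sets(
        contigs, config, rate_multipliers=multipliers, gene_map=gene_map
    )
    matrix, truth_mark = generate_genotype_matrix(config)
    truth = GroundTruth(
        variants=truth_var.variants,
        markers=truth_mark.markers,
        categories=truth_cat.categories,
    )
    return SynthBundle(
        config=config,
        contigs=contigs,
        hits=hits,
        gene_map=gene_map,
        set_a=set_a,
        set_b=set_b,
        matrix=matrix,
        annotations=annotations,
        go_edges=edges,
        truth=truth,
    )
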