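"""Readers and writers for the pipeline's file formats.

Formats are the ones the corresponding real-world tools exchange: FASTA for
reference contigs (via Biopython), a VCF dialect for caller call sets (INFO
keys MQ, MMLQ, QD, PP, SbPval, HapScore, MGOF, SC; allelic depths in the
sample AD field; read back through pysam), TSV for the hit table, contig
stats, catalog, genotype matrix and annotations, child-TAB-parent TSV (or a
minimal ``is_a``-only OBO subset via obonet) for the ontology, and JSON for
summaries.  All writers are deterministic: identical in-memory objects
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import CallerVariant, ConsensusSNP, ContigRecord
from .enrichment import AnnotationTable
from .errors import InputValidationError
from .genotyping_qc import GenotypeMatrix
from .pairing import TargetHit

__all__ = [
    "write_fasta", "read_fasta",
    "write_contig_stats", "read_contig_stats",
    "write_hit_table", "read_hit_table",
    "write_caller_vcf", "read_caller_vcf",
    "write_catalog", "read_catalog",
    "write_genotype_matrix", "read_genotype_matrix",
    "read_genomestudio_table",
    "write_annotations", "read_annotations",
    "write_go_edges", "read_go_edges", "read_obo_edges",
    "write_json", "read_json",
]

_INFO_KEYS = ("MQ", "MMLQ", "QD", "PP", "SbPval", "HapScore", "MGOF", "SC")


# ---------------------------------------------------------------- reference

def write_fasta(contigs: Iterable[ContigRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.contig_id, description="")
        for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(
    path: str | Path, depths: Mapping[str, float] | None = None
) -> list[ContigRecord]:
    """Load contigs; mean depths come from ``depths`` (default 0)."""
    depths = depths or {}
    return [
        ContigRecord(rec.id, str(rec.seq), float(depths.get(rec.id, 0.0)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_contig_stats(contigs: Iterable[ContigRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"contig_id": c.contig_id, "length": c.length, "mean_depth": c.mean_depth}
            for c in contigs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_contig_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip").set_index("contig_id")


# ---------------------------------------------------------------- hit table

def write_hit_table(hits: Iterable[TargetHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "contig_id": h.contig_id, "gene_id": h.gene_id,
                "identity": h.identity, "evalue": h.evalue,
                "mean_coverage": h.mean_coverage, "contig_length": h.contig_length,
            }
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> list[TargetHit]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {
        "contig_id", "gene_id", "identity", "evalue", "mean_coverage",
        "contig_length",
    }
    missing = required - set(df.columns)
    if missing:
        raise InputValidationError(f"hit table lacks columns: {sorted(missing)}")
    return [
        TargetHit(
            contig_id=str(r.contig_id), gene_id=str(r.gene_id),
            identity=float(r.identity), evalue=float(r.evalue),
            mean_coverage=float(r.mean_coverage),
            contig_length=int(r.contig_length),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------- VCF dialect

def write_caller_vcf(
    variants: Sequence[CallerVariant],
    contigs: Sequence[ContigRecord],
    path: str | Path,
    caller_id: str = "A",
) -> None:
    """Write one caller's call set as an uncompressed VCF.

    Quality annotations go into INFO; read counts into the single POOL
    sample's AD field (ref then each alt).  Missing annotations are omitted.
    """
    lines = ["##fileformat=VCFv4.2", f"##source=caller{caller_id}"]
    for c in contigs:
        lines.append(f"##contig=<ID={c.contig_id},length={c.length}>")
    for key in _INFO_KEYS:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">'
        )
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tPOOL")
    for v in sorted(variants, key=lambda x: (x.contig_id, x.pos)):
        info_parts = [
            f"{k}={getattr(v, k):.6g}"
            for k in _INFO_KEYS
            if getattr(v, k) is not None
        ]
        info = ";".join(info_parts) if info_parts else "."
        ad = ",".join(str(x) for x in (v.ref_reads, *v.alt_reads))
        lines.append(
            "\t".join(
                [
                    v.contig_id, str(v.pos), ".", v.ref, ",".join(v.alts),
                    ".", ".", info, "AD", ad,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_caller_vcf(path: str | Path, caller_id: str = "A") -> list[CallerVariant]:
    """Read a caller call set back through pysam."""
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = {k: rec.info.get(k) for k in _INFO_KEYS}
            ad = rec.samples[0].get("AD") or (0,)
            variants.append(
                CallerVariant(
                    caller_id=caller_id,
                    contig_id=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    ref_reads=int(ad[0]),
                    alt_reads=tuple(int(x) for x in ad[1:]),
                    **{
                        k: (float(x) if x is not None else None)
                        for k, x in info.items()
                    },
                )
            )
    return variants


# ------------------------------------------------------------------ catalog

def write_catalog(snps: Iterable[ConsensusSNP], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "contig_id": s.contig_id, "pos": s.pos, "ref": s.ref,
                "alt": s.alt, "depth": s.depth, "maf": s.maf,
                "flank_up": s.flank_up, "flank_down": s.flank_down,
                "gene_id": s.gene_id if s.gene_id is not None else "",
            }
            for s in snps
        ]
    ).to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> list[ConsensusSNP]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     float_precision="round_trip")
    return [
        ConsensusSNP(
            contig_id=str(r.contig_id), pos=int(r.pos), ref=str(r.ref),
            alt=str(r.alt), depth=int(r.depth), maf=float(r.maf),
            flank_up=str(r.flank_up), flank_down=str(r.flank_down),
            gene_id=str(r.gene_id) or None,
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------- genotype matrix

def write_genotype_matrix(
    matrix: GenotypeMatrix, calls_path: str | Path, markers_path: str | Path
) -> None:
    """Wide calls TSV (replicate pairs recorded in a header comment) plus a
    marker metadata TSV."""
    pairs = ";".join(f"{a},{b}" for a, b in matrix.replicate_pairs)
    with open(calls_path, "w") as fh:
        fh.write(f"#replicate_pairs={pairs}\n")
        matrix.calls.to_csv(fh, sep="\t", index_label="marker_id")
    matrix.markers.to_csv(markers_path, sep="\t", index_label="marker_id")


def read_genotype_matrix(
    calls_path: str | Path, markers_path: str | Path
) -> GenotypeMatrix:
    with open(calls_path) as fh:
        first = fh.readline()
        pairs: list[tuple[str, str]] = []
        if first.startswith("#replicate_pairs="):
            spec = first.split("=", 1)[1].strip()
            if spec:
                pairs = [tuple(p.split(",")) for p in spec.split(";")]  # type: ignore[misc]
            calls = pd.read_csv(fh, sep="\t", index_col="marker_id")
        else:
            fh.seek(0)
            calls = pd.read_csv(fh, sep="\t", index_col="marker_id")
    markers = pd.read_csv(markers_path, sep="\t", index_col="marker_id",
                          float_precision="round_trip")
    return GenotypeMatrix(calls=calls, markers=markers.loc[calls.index],
                          replicate_pairs=pairs)


def read_genomestudio_table(path: str | Path) -> GenotypeMatrix:
    """Reader for a GenomeStudio-style "Full Data Table" export.

    Expects a ``Name`` column, a ``GenTrain Score`` column, and one
    ``<sample>.GType`` column per sample with values AA/AB/BB/NC.  All
    markers are labelled ``predicted``; replicate pairs are not encoded in
    this format.
    """
    df = pd.read_csv(path, sep="\t")
    if "Name" not in df.columns or "GenTrain Score" not in df.columns:
        raise InputValidationError(
            "GenomeStudio table needs 'Name' and 'GenTrain Score' columns"
        )
    gtype_cols = [c for c in df.columns if c.endswith(".GType")]
    if not gtype_cols:
        raise InputValidationError("GenomeStudio table has no .GType columns")
    calls = df.set_index("Name")[gtype_cols]
    calls.columns = [c[: -len(".GType")] for c in gtype_cols]
    calls.index.name = "marker_id"
    markers = pd.DataFrame(
        {
            "gentrain_score": df.set_index("Name")["GenTrain Score"],
            "source": "predicted",
        }
    )
    markers.index.name = "marker_id"
    return GenotypeMatrix(calls=calls, markers=markers, replicate_pairs=[])


# -------------------------------------------------------------- annotations

def write_annotations(annotations: AnnotationTable, path: str | Path) -> None:
    genes = sorted(
        set(annotations.go)
        | set(annotations.family)
        | annotations.orphan
        | annotations.conifer_specific
    )
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g,
                "go_terms": ";".join(sorted(annotations.go.get(g, ()))),
                "family": annotations.family.get(g, ""),
                "orphan": int(g in annotations.orphan),
                "conifer_specific": int(g in annotations.conifer_specific),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    go: dict[str, set[str]] = {}
    family: dict[str, str] = {}
    orphan: set[str] = set()
    conifer: set[str] = set()
    for r in df.itertuples():
        gene = str(r.gene_id)
        if r.go_terms:
            go[gene] = set(str(r.go_terms).split(";"))
        if r.family:
            family[gene] = str(r.family)
        if int(r.orphan):
            orphan.add(gene)
        if int(r.conifer_specific):
            conifer.add(gene)
    return AnnotationTable(
        go=go, family=family, orphan=orphan, conifer_specific=conifer
    )


def write_go_edges(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for child, parent in edges:
            fh.write(f"{child}\t{parent}\n")


def read_go_edges(path: str | Path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child, parent = line.split("\t")
            edges.append((child, parent))
    return edges


def read_obo_edges(path: str | Path) -> list[tuple[str, str]]:
    """Extract (child, parent) ``is_a`` edges from a minimal OBO file."""
    import obonet

    graph = obonet.read_obo(str(path))
    # obonet orients edges child -> parent for is_a
    return [
        (child, parent)
        for child, parent, key in graph.edges(keys=True)
        if key == "is_a"
    ]


# --------------------------------------------------------------------- JSON

def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
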