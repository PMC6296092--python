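"""Shared fixtures: one synthetic study bundle reused across test modules."""

from __future__ import annotations

import math

import pytest

from snpcatalog import (
    apply_quality_filters,
    filter_hits,
    intersect_callsets,
    pair_and_summarize,
)
from snpcatalog.abundance import aggregate_genes, contig_abundance, rank_genes
from snpcatalog.synthdata import SynthConfig, SynthBundle, simulate_study


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig(rng_seed=1)


@pytest.fixture(scope="session")
def bundle(default_config) -> SynthBundle:
    return simulate_study(default_config)


@pytest.fixture(scope="session")
def pipeline_products(bundle):
    """Run the in-memory pipeline on the shared bundle once.

    Returns a dict with the retained hits, contig->gene map, matched pairs,
    passing pairs, audit, ranked gene abundances and the top-decile set.
    """
    retained = filter_hits(bundle.hits)
    pairing = pair_and_summarize(retained, bundle.config.n_genes)
    gene_of = {h.contig_id: h.gene_id for h in pairing.retained_hits}
    common, union = intersect_callsets(bundle.set_a, bundle.set_b)
    passing, audit = apply_quality_filters(common)
    by_contig = bundle.contig_by_id
    snp_counts: dict[str, int] = {}
    for p in passing:
        snp_counts[p.a.contig_id] = snp_counts.get(p.a.contig_id, 0) + 1
    parts_by_gene: dict[str, list] = {}
    for contig_id, gene in gene_of.items():
        c = by_contig[contig_id]
        if math.floor(c.mean_depth) < 2:
            continue
        parts_by_gene.setdefault(gene, []).append(
            contig_abundance(
                contig_id, snp_counts.get(contig_id, 0), c.length, c.mean_depth
            )
        )
    ranked, top = rank_genes(aggregate_genes(parts_by_gene))
    return {
        "retained": retained,
        "pairing": pairing,
        "gene_of": gene_of,
        "common": common,
        "union": union,
        "passing": passing,
        "audit": audit,
        "ranked": ranked,
        "top": top,
    }
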