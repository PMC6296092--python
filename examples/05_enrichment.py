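"""Functional enrichment among the most polymorphic genes.

Runs the pipeline to rank genes by beta, then tests GO terms (one-sided
Fisher after true-path propagation, nodesize 5), gene families (two-sided,
>= 2 members in the top decile, Benjamini-Hochberg adjusted) and binary
flags.  The generator plants one enriched family and one enriched GO term,
which the tests should recover.
"""

import math

from snpcatalog import (
    apply_quality_filters,
    family_tests,
    filter_hits,
    fisher_term_tests,
    flag_tests,
    intersect_callsets,
    pair_and_summarize,
    propagate_go,
)
from snpcatalog.abundance import aggregate_genes, contig_abundance, rank_genes
from snpcatalog.synthdata import DESIGNATED_FAMILY, DESIGNATED_TERM, SynthConfig, simulate_study

bundle = simulate_study(SynthConfig(rng_seed=1))
retained = filter_hits(bundle.hits)
pairing = pair_and_summarize(retained, bundle.config.n_genes)
common, _ = intersect_callsets(bundle.set_a, bundle.set_b)
passing, _ = apply_quality_filters(common)

counts: dict[str, int] = {}
for p in passing:
    counts[p.a.contig_id] = counts.get(p.a.contig_id, 0) + 1
parts: dict[str, list] = {}
for h in pairing.retained_hits:
    c = bundle.contig_by_id[h.contig_id]
    if math.floor(c.mean_depth) < 2:
        continue
    parts.setdefault(h.gene_id, []).append(
        contig_abundance(h.contig_id, counts.get(h.contig_id, 0),
                         c.length, c.mean_depth)
    )
ranked, top = rank_genes(aggregate_genes(parts))
universe = set(parts)
print(f"genes ranked: {len(ranked)}, top decile: {len(top)}")

go = {g: t for g, t in bundle.annotations.go.items() if g in universe}
full = propagate_go(go, bundle.go_edges)
terms = fisher_term_tests(full, top & set(full), set(full), bundle.go_edges)
print("\nmost enriched GO terms (one-sided Fisher, raw p):")
for r in terms[:3]:
    marker = "  <- planted" if r.category == DESIGNATED_TERM else ""
    print(f"  {r.category:10s} p={r.p_value:.2e} ({r.a}/{r.a + r.c} in top)"
          f"{marker}")

families = family_tests(bundle.annotations, top, universe)
print("\nmost enriched families (two-sided Fisher, BH-adjusted):")
for r in families[:3]:
    marker = "  <- planted" if r.category == DESIGNATED_FAMILY else ""
    print(f"  {r.category:14s} p={r.p_value:.2e} q={r.p_adjusted:.2e}{marker}")

for flag in ("conifer_specific", "orphan"):
    r = flag_tests(bundle.annotations, top, universe, flag)
    print(f"\n{flag}: {100 * r.extra['prop_top']:.1f}% of top vs "
          f"{100 * r.extra['prop_rest']:.1f}% of rest (p = {r.p_value:.3f})")
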