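"""Array candidate selection and marker quality control.

Candidate SNPs need clean 50 bp flanks (no other raw variant from either
caller), 20 bp clearance from contig ends and a functionality score >= 0.60;
one SNP is chosen per gene.  Genotyped markers are then classified as valid,
monomorphic, paralogous (heterozygote excess Fe >= 0.80) or other failures,
and the true-positive-rate report tallies the classes per SNP source.
"""

from snpcatalog import classify_matrix, replicate_concordance, tpr_report
from snpcatalog.array_design import VariantIndex, select_candidates
from snpcatalog.catalog import apply_quality_filters, build_consensus_snp, intersect_callsets
from snpcatalog.synthdata import SynthConfig, sample_functionality_scores, simulate_study

bundle = simulate_study(SynthConfig(rng_seed=1))

common, _ = intersect_callsets(bundle.set_a, bundle.set_b)
passing, _ = apply_quality_filters(common)
gene_of = dict(zip(bundle.gene_map.index, bundle.gene_map["gene_id"]))
snps = [
    build_consensus_snp(p, bundle.contig_by_id[p.a.contig_id].sequence,
                        gene_of[p.a.contig_id])
    for p in passing
]
index = VariantIndex([*bundle.set_a, *bundle.set_b])
scores = sample_functionality_scores([(s.contig_id, s.pos) for s in snps], seed=1)
lengths = {c.contig_id: c.length for c in bundle.contigs}
candidates = select_candidates(snps, scores, index, lengths)
selected = [c for c in candidates if c.selected]
print(f"catalog SNPs evaluated: {len(candidates)}")
print(f"clean flanks:           {sum(c.clean_flanks for c in candidates)}")
print(f"selected (1 per gene):  {len(selected)}")

qc = classify_matrix(bundle.matrix)
report = tpr_report(qc)
print("\nmarker QC by source (valid/mono/paralog/other, success %):")
for source, row in report.rows.iterrows():
    print(f"  {source:10s} {int(row['valid']):5d} {int(row['monomorphic']):4d} "
          f"{int(row['paralogous']):4d} {int(row['other_fail']):4d}  "
          f"{row['success_rate']:.1f}%")
pct, cells = replicate_concordance(bundle.matrix)
print(f"replicate concordance: {pct:.2f}% over {cells} cells")
# success_rate is the fraction of manufactured markers yielding valid,
# segregating assays - the array's true positive rate for predicted SNPs.
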