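"""Generate a synthetic exome-capture study with known ground truth.

Builds reference contigs, two caller call sets, a genotype matrix and
functional annotations, then prints the headline counts.  Every downstream
example starts from a bundle like this one.
"""

from snpcatalog.synthdata import SynthConfig, simulate_study

config = SynthConfig(rng_seed=1)
bundle = simulate_study(config)

truth = bundle.truth.variants
print(f"contigs:            {len(bundle.contigs)}")
print(f"caller A variants:  {len(bundle.set_a)}")
print(f"caller B variants:  {len(bundle.set_b)}")
print(f"called by both:     {int(truth['in_both_callers'].sum())}")
print(f"truth-passing SNPs: {int(truth['passes_quality'].sum())}")
print(f"array markers:      {len(bundle.matrix.calls)} "
      f"({(bundle.truth.markers['true_class'] == 'valid').sum()} valid by truth)")

# The counts above are construction-time labels: the generator knows which
# variants both callers saw and which were planted to fail a quality filter,
# so the pipeline's recovery of these numbers can be checked exactly.
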