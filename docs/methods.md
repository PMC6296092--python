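# Methods

## Scope and model

`snpcatalog` implements the computational core of a dual-caller
exome-capture SNP discovery study in a non-model plant genome, from the
contig-to-target pairing step through catalog construction, abundance
analysis, array design, genotyping QC and functional enrichment.  Running
the assembler, aligners, variant callers, BLAST or the array-manufacturing
software is out of scope: their outputs (hit tables, call sets with quality
annotations, genotype matrices with clustering scores, functionality
scores) are inputs to this package, either read from files or produced by
the synthetic generator.

## Consensus catalog

Two callers are assumed: an annotation-rich one ("caller A", the
Platypus-style caller whose INFO fields MQ, MMLQ, QD, PP, SbPval, HapScore,
MGOF and SC drive the quality cascade) and a confirmation-only one
("caller B").  A site is *common* when both callers report the same contig,
1-based position, reference allele and normalized alternative-allele tuple;
allele strings are upper-cased before comparison and sites that disagree on
alleles are not matched.  Multi-allelic matched sites are carried into the
filter cascade, where the bi-allelic criterion rejects them and the audit
attributes the rejection — keeping every exclusion visible in one place
rather than silently dropping sites at intersection.

The cascade is a pure conjunction: order-independent, with every violated
criterion of a rejected site tallied, so audit totals can exceed rejection
counts.  Depth and minor-allele frequency come from caller A's read counts
(MAF = min(f, 1 − f) of the alternative-read fraction); using a single
source avoids double counting.  Two deliberately configurable readings:

* **MGOF** is applied as printed, a lower bound (≥ 20), although a
  goodness-of-fit cap would conventionally be an upper bound; the
  `mgof_inverted` switch flips it for sensitivity analysis.  The intent of
  the original criterion is not guessed.
* The number reported as SNPs "not in the intersection" equals
  |A| + |B| − |A∩B|; the package computes and labels it as the union size.

Flanks are the up-to-100-bp sequences on either side of a SNP, truncated at
contig ends and excluding the variant base.

## SNP abundance (β)

β = [(S + 1)/L] / H(⌊D⌋ − 1) with H(n) the n-th harmonic number.  Under a
Watterson-style view, the expected number of segregating sites observed in
a contig sequenced at depth D grows like θ·L·H(D − 1); dividing the
(pseudocounted) per-bp SNP count by the harmonic number therefore removes
the mechanical depth effect and leaves an estimate proportional to θ.  Two
consequences worth noting:

* the correction presumes depth-coupled discovery.  If S were generated
  independently of D, dividing by H(D − 1) would *introduce* a negative
  depth association; the tests assert exactly this pair of behaviors.
* D is a mean, hence rarely integral.  The harmonic sum needs an integer
  limit; the default floors D (conservative), and a `depth_mode =
  "interpolate"` option uses the analytic continuation H(x) = ψ(x + 1) + γ
  for sensitivity analysis.  Contigs with ⌊D⌋ < 2 leave the sum empty and
  are excluded from abundance analysis with a logged warning; the upstream
  coverage filter (≥ 25) makes this a synthetic-edge-case concern only.

Genes composed of several contigs receive the length-weighted mean of their
contig βs.  Ranking is by descending weighted β with deterministic
tie-breaks (descending total SNPs, then gene id); the top decile holds
⌊0.10·N⌋ genes (at least one).

## Array design and genotyping QC

Candidate eligibility uses the stricter readings of the published
distances: the 50 bp exclusion window is closed at both bounds and is
checked against the union of both callers' *raw* call lists regardless of
filter status (any underlying polymorphism can disrupt probe annealing; a
switch restricts the check to filtered SNPs), and the 20 bp end rule means
min(pos − 1, L − pos) ≥ 20.  Within a gene the highest functionality score
wins, ties broken by higher MAF then lower position.

Marker classification precedence: signal gates first (GenTrain-style score
< 0.13 or call rate < 80 % → `other_fail`), then a single homozygous class
→ `monomorphic`, then Fₑ ≥ 0.80 → `paralogous`, else `valid`.  An
all-heterozygote marker is paralogous (Fₑ = 1), not monomorphic.  The
heterozygote-excess statistic is not uniquely pinned down by its published
use, so the default is Fₑ = (Hₒ − Hₑ)/(1 − Hₑ) clamped at zero, with
Fₑ = Hₒ/Hₑ − 1 available behind `fe_mode="ratio"`; the two agree at the
extremes that drive classification (Fₑ = 1 for obligate heterozygotes, 0 at
Hardy–Weinberg proportions).  Replicate concordance is the fraction of
(marker, pair) cells with both members called that agree, over designated
replicate sample pairs.

## Enrichment

GO annotations are closed under the true-path rule over a child→parent DAG
before testing.  Term tests are one-sided Fisher's exact tests (raw,
unadjusted p-values, as is conventional for hierarchy-aware GO scoring);
terms annotating fewer than `nodesize = 5` universe genes are skipped.  Two
hierarchy treatments are provided: `classic` and `elim` (leaves-upward; the
genes of terms significant at α = 0.01 are removed from their ancestors
before those are tested).  The `weight01`-style decorrelation mixture is
intentionally not re-implemented; `elim` covers the hierarchy-aware case
and reports state the method used.  Family tests are two-sided, restricted
to families with ≥ 2 members in the top decile, with Benjamini–Hochberg
adjustment (the correction method is a package choice; the source procedure
named none).  Flag tests (orphan, conifer-specific) are single two-sided
tests reported with group proportions.  Universes follow the study design:
GO tests use only genes carrying annotations in the namespace under test;
family and flag tests use all paired genes (configurable).

## Synthetic generator

The generator emulates, at reduced scale, the study conditions the pipeline
was built for; its defaults are fixed study parameters, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| caller Jaccard | 0.285 | the study's intersection/union ratio (68,004 / 238,666) |
| filter-fail fraction | 0.09 | 1 − 61,771/68,004 of intersection sites failing the cascade |
| true SNP rate | 0.003 /bp | near the observed ~0.23 SNPs/100 bp after ~60–70 % detection losses |
| contig length range | 400–2000 bp | straddles the 500 bp gate; mean near the ~1 kb assembly average |
| mean depth range | 10–900 reads | spans both sides of the [25, 800] usable window |
| marker classes | 9 % paralog, 5.5 % monomorphic, 1.3 % other | the validation array's failure-class proportions |
| valid-marker MAF | U(0.05, 0.5), Hardy–Weinberg | a breeding panel with rare alleles under-represented |
| paralog markers | P(AB) = 0.95 | probes annealing to two fixed paralogous loci |
| enrichment | 12 genes sharing one family and one GO term, SNP rate × 6 | a detectable planted signal |

Each intersection site planted to fail does so on exactly one criterion,
cycling through all ten (including a singleton with one alternative read
and a tri-allelic site), which makes per-criterion attribution testable.
Passing sites draw their annotations comfortably inside every bound.
Genotype matrices append two replicate columns duplicating the first two
samples; class-defining properties (a valid marker really segregates, a
paralog marker's realized heterozygote excess clears 0.80) are enforced by
bounded resampling at construction so that ground-truth labels are exact at
zero genotype-error rate.  All randomness flows through per-operation
`numpy` generators seeded from the config, so identical configs give
byte-identical outputs.

The null-calibration generator draws term sizes uniformly in 50–400 over a
2,000-gene universe: tables large enough that the discrete Fisher test
attains a size near its nominal level, which is what a calibration check
presumes (tiny terms would make the test conservative by discreteness, a
property of the test, not a bug in calibration).

What the generator does *not* emulate: read-level errors, capture-probe
thermodynamics, linkage between sites, assembly artifacts, allele-frequency
spectra of natural populations.  Passing tests therefore demonstrate that
the pipeline's logic recovers planted truth exactly and that its statistics
behave as designed — not that any particular biological dataset would yield
particular values.

## Problem sizes and numerics

Test and acceptance runs use scaled-down instances chosen to exercise every
code path: 200–1,500 genes, 300–3,000 contigs, ≥ 10⁴ variant sites for
filter-recovery checks, 2,000 × 200 genotype matrices, 100-seed replications
for stochastic properties, and a 10,000-cell constructed fixture for the
replicate-concordance arithmetic.  β values are validated against an
explicit harmonic-loop oracle to 10⁻¹²; Fisher p-values against explicit
hypergeometric tail sums (exhaustively for small tables, randomized up to
N = 500).  Summary ratios are kept at full precision internally and rounded
(2 dp for per-gene ratios, 1 dp for rates) only in reports.

## Known limitations

* The `elim` implementation processes testable terms in topological order
  of the full DAG; terms below `nodesize` are skipped but their genes still
  count at ancestors, matching the usual practice.
* The GenomeStudio-style reader covers the minimal "Full Data Table" layout
  (Name, GenTrain Score, per-sample `.GType` columns) only.
* The pairing stage's CLI wiring takes the number of targeted genes from
  the synthetic config; library users supply it directly.
* Pre-filter capture efficiency (pairing before the coverage screen) is not
  reproduced; only the post-filter recovery accounting is, since the
  pre-filter criteria are not part of the published procedure.
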