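# Methods

This note records the models, parameter choices and numerical conventions
behind `repmeth`, and what the synthetic benchmarks do and do not show.

## Data model and coordinates

A methylome sample is a map from CpG dinucleotides to (methylated,
unmethylated) read-count pairs. Three coordinate dialects coexist and are
converted at the boundaries:

* cytosine reports use the 1-based position of each cytosine, per strand;
* the per-CpG coverage dialect uses 1-based start = end rows;
* all interval annotations (repeats, TSS, ICRs) are 0-based half-open BED.

Strand merging sums the plus-strand C (position *p*) and the minus-strand C
(position *p* + 1) onto *p*, giving one canonical key per dinucleotide; a
CpG covered on one strand only passes through unchanged. Duplicate input
records for the same (chrom, pos, strand) are an error, not silently
summed — deduplication is an upstream responsibility. Interval membership
of a CpG is decided by half-open containment of the 0-based coordinate of
its plus-strand C, so a CpG exactly at a region start is inside and one at
the region end is outside.

## Library equalisation

Sequencing depth differs between libraries; the deeper library is thinned
so that scores are compared at matched depth. Because the pipeline starts
from count tables rather than reads, thinning is per-site binomial: every
count is replaced by a Binomial(count, ratio) draw with ratio =
total_small / total_large. This preserves each site's expected methylation
fraction and the expected total matches read-level subsampling; the two
differ only in higher-order statistics of the coverage distribution. A
seed is a required argument — there is no silent clock seeding anywhere in
the package.

## CpG qualification and region scoring

Two filters gate the two-sample repeat analysis, applied per CpG:

* **minimum coverage** `min_cov = 8` in both samples (coverage exactly 8
  passes);
* **coverage-bias rule** `min(cov) ≥ bias_fraction · max(cov)` with
  `bias_fraction = 0.6`. The phrase "the lowest coverage must be within
  60% of the other" admits a second reading — relative deviation
  `(max−min)/max ≤ 0.6` — which is implemented behind the `bias_rule`
  switch (`"ratio"` default, `"deviation"` alternative). The ratio
  reading is the default because it is the more literal one. Note the
  coverage minimum dominates at low depth: a (10, 6) pair satisfies the
  bias arithmetic but is removed by `min_cov` first.

An element is scored only with at least `min_cpgs = 8` qualifying CpGs;
elements below the threshold are excluded and counted, never imputed. The
score is the coverage-weighted mean of per-CpG methylation percentages,
each sample weighted by its own coverages (no pooling across samples).
The weighted mean is algebraically identical to normalising each CpG by
the region's total reads and summing, and — when computed from counts —
to the pooled fraction 100·Σm/Σ(m+u).

Window and ICR scoring deliberately relax the two-sample filters
(`min_cov = 1`, no bias rule, any covered CpG counts): the genome-wide
survey and the purity check describe each sample on its own and precede
the stringent element-level comparison. Windows tile each chromosome from
coordinate 0; the last window may be short. The ICR purity flag marks
maternally methylated ICRs scoring below 15% in both samples — the
expected sperm pattern; paternal ICRs are reported but not flagged.

## Differential calling and statistics

* A call requires |Δ| strictly greater than `dm_threshold_pp = 10`
  percentage points, with Δ = mutant − wild type; "hypo" means lower in
  the mutant.
* The distribution-shift test is a Mann–Whitney U of the mutant score
  vector against the wild-type score vector, midranks for ties, exact
  enumeration when both n ≤ 20 and the data are tie-free, otherwise the
  tie-corrected normal approximation. The `scope` argument selects the
  called subset (default) or all scored elements; the defaults keep both
  routes available because either population is a defensible input to the
  test.
* Subfamily tables sort by total calls descending with lexicographic
  tie-breaks and truncate to the 20 most frequent subfamilies.
* TSS proximity counts a call when the gap between the element boundary
  and the nearest TSS is ≤ 10 kb (inclusive; 0 when the TSS is inside the
  element).
* Control analyses run the identical score/call/shift machinery on LINE1
  and B1 annotations and on random 1-kb regions (uniform starts,
  chromosomes chosen proportional to length; 1,000 regions by default at
  desk scale).
* No multiple-testing correction is applied anywhere; reports carry an
  explicit note to that effect.

Coat-colour penetrance uses Pearson chi-squared on pooled 2×3 Y/M/psi
tables without continuity correction, collapsing categories empty in both
groups (df reduces accordingly) and flagging expected counts below 5;
genotype ratios are tested with a goodness-of-fit chi-squared. The
five-category coat score maps percent yellow as: 100 → yellow,
(95, 100) → yellow-mottled, (25, 95] → mottled, [5, 25] →
pseudoagouti-mottled, [0, 5) → pseudoagouti. The published category edges
are verbally inconsistent at the margins (category assignment is by
trained observer in practice); the half-open conventions above make the
mapping total and deterministic, which is all the downstream pooling
needs. Non-carriers of *A<sup>vy</sup>* must be excluded before any
penetrance computation.

Sanger clone statistics: conversion rate is the percentage of converted
non-CpG cytosines with a 97% QC bar (exactly 97% passes); an individual's
methylation is the percentage of methylated calls pooled over all clones
(not a mean of per-clone percentages — pooling matches how individuals
are summarised in lollipop figures and weights clones by their observed
calls); missing calls leave both numerator and denominator. The genotype
comparison is a two-sided Welch t-test on per-individual percentages —
chosen over the pooled-variance variant (still available) because group
sizes of 2–3 individuals make the equal-variance assumption unverifiable.
Two degenerate zero-variance groups with equal means return p = 1 by
convention.

## The simulator

The generator emulates the structure of the real inputs, not their
sequence content:

* **Genome.** Two 3-Mb chromosomes; CpG positions with geometric spacing,
  mean 100 bp (the genome-wide CpG density of mouse is of this order).
* **Repeats.** 2,000 ERVK-like elements in four labelled subfamilies
  (IAPEY, RLTRETN, IAPLTR3, RNERVK23-int) of 1.2 kb, plus 400 LINE1-like
  (1.5 kb) and 400 B1-like (1 kb) control elements, placed without
  overlap. Element lengths are chosen so a typical element carries enough
  CpGs to pass the ≥ 8-CpG filter; they do not mimic true repeat length
  distributions (real B1 elements are ~150 bp and would essentially never
  be individually scorable).
* **Methylation.** One true level per element drawn from Beta(27, 3)
  (mean 0.90, sd ≈ 0.054 — regional methylation near 90%), shared between
  the samples; background CpGs draw per-CpG levels from the same beta;
  ICR CpGs are overridden to 3% (maternal) or 90% (paternal) in both
  samples. Planted effects shift the mutant level of a chosen fraction of
  a subfamily by a subtractive percentage-point delta, clamped to [0, 1] —
  subtractive rather than multiplicative so the planted delta is directly
  comparable to the pipeline's Δ. The default plants −25 pp in 1/6 of the
  IAPEY elements (100 of 2,000 ERVK).
* **Coverage.** Negative binomial per CpG per sample, mean 30, size 10
  (sd ≈ 11), independent across samples; a configurable imbalance
  multiplier exercises the bias filter. Methylated counts are binomial at
  the true level. Under these defaults roughly half the elements pass the
  qualification filters, which is the regime the filters are designed
  for.
* **Cohorts and clones.** Multinomial Y/M/psi cohorts (defaults: 29/56/15%
  for a control cross and 47/41.8/11.2% for the mutant-sire cross — the
  yellow fractions are the observed ones, the M:psi split of the second
  group keeps the control's M:psi ratio since only the yellow fraction is
  reported); clone matrices are Bernoulli at 59% (wild type) vs 26%
  (mutant) over 3 individuals × 10 clones × 20 CpGs with 99% conversion
  efficiency.

All randomness flows from one root seed through named sub-streams
(genome, methylome, cohort, clones, strand split), so components can be
regenerated independently. Fixture emission splits each CpG's counts
binomially over the two strands so that reading the files back through
strand merging reproduces the in-memory samples exactly.

### What the benchmarks show — and do not

With a −25 pp effect at 30× and ≥ 8 qualifying CpGs per element, the
per-element measurement noise on Δ is ~2–3 pp, so recovery of planted
elements is essentially perfect (mean sensitivity 1.0, FPR < 0.001 over
20 seeds) and the no-effect calibration is conservative (the two score
vectors are paired through a shared true level, so the unpaired
Mann–Whitney is conservative under the null). These numbers certify the
machinery — filters, weighting, calling, tests — against known truth.
They do not certify performance on real data, where true levels vary
along elements, coverage is locally correlated (mappability, PCR),
bisulphite conversion is imperfect, and repeat mappability biases which
elements are measurable at all. In particular the simulator draws one
level per element, so it cannot probe sensitivity to within-element
methylation heterogeneity.

## Problem sizes

Desk-scale defaults — a 6-Mb genome, ~60,000 CpGs per sample, 2,800
elements, 20-seed replications, 100 cohort and 50 clone replicates — keep
a full test run and the acceptance script each under a minute while
leaving every statistical check well-powered; all sizes are ordinary
config fields and scale up unchanged.

## Known limitations

* The equalisation thinning is count-level; exact reproduction of a
  read-level subsample (including its unseeded randomness) is not
  possible from count tables.
* `shift_test` offers both populations (all scored elements / called
  subset) because the appropriate scope is analysis-dependent; results
  should state which was used (the run summary records it).
* The coat-category band edges are a convention over verbally
  inconsistent definitions; only the pooled three-group counts feed any
  statistic.
* Clone matrices carry no within-individual clone structure (each call is
  independent Bernoulli), so clone-level pseudo-replication effects are
  not modelled.
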