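# Methods

## Data model

An expression study is a gene × sample matrix of log10 intensities with a
matching matrix of per-observation detection p-values and a sample sheet
assigning each array to a condition group, a compartment (TL = translatome,
RNA from heavy polysome fractions; TR = transcriptome, total RNA) and a
replicate index. A contrast compares a test group against a reference group
inside one compartment; the translational-switch analysis pairs a TL
contrast with the matching TR contrast.

## Differential engine

1. **Detection filter.** A gene enters the analysis when its detection
   p-value is ≤ 0.02 in at least ⌈n/2⌉ samples of at least one of the two
   contrast groups. The per-group majority rule is one of three selectable
   readings of a per-observation detection cut ("half", "all", "any");
   "half" is the default because it keeps genes expressed in only one
   condition — exactly the genes a switch analysis is about — while
   discarding noise-level probes.
2. **Z-score normalization.** Each sample column is standardized over the
   retained genes with the population SD. A constant column is an error.
   Z-scoring makes arrays comparable without a reference distribution and
   is invariant to per-sample affine intensity rescaling.
3. **Z-ratio.** Difference of group-mean Z-scores per gene, divided by the
   population SD of those differences across all retained genes. The
   denominator makes the statistic self-normalizing: its scale adapts to
   the overall spread of effects in the contrast. Identical test/reference
   groups give an all-zero, warned result rather than 0/0.
4. **Per-gene p-values.** Two-sample two-tailed t-test on the per-sample
   Z-scores, equal-variance by default (Welch by flag). Zero-variance
   guards: identical groups give p = 1.
5. **Variance exclusion.** Default rule excludes genes whose pooled
   within-group SD of Z-scores exceeds the 95th percentile across genes
   (quantile 1.0 disables). An alternative "anova" mode excludes genes with
   one-way ANOVA p < threshold across replicate batches. The quantile rule
   is the default because the batch reading requires a replicate pairing
   that not every design has; both are recorded in run metadata.
6. **Empirical FDR.** Label-permutation tail-area FDR: group labels inside
   the contrast are reassigned, the mean-Z differences recomputed, and for
   each gene's threshold t = |z_ratio| the FDR estimate is the mean
   permutation count of null |z*| ≥ t divided by the observed count ≥ t,
   capped at 1. Two calibration choices matter and are deliberate:
   - the observed label assignment is **excluded** from the null (a 3v3
     design yields 9 informative splits out of 10 distinct unordered
     splits); including it would place every gene's own statistic in its
     null pool and floor the FDR at 1/n_permutations;
   - permuted differences are scaled by the **observed** cross-gene SD, not
     each permutation's own. The observed denominator is what shrinks the
     real z_ratios; re-standardizing every permutation inflates the null
     tail whenever a substantial share of genes is truly regulated. On null
     data the two scalings coincide in distribution.
   The per-gene values are smoothed q-value style (running minimum along
   ascending |z_ratio|), so FDR is non-increasing in |z_ratio|. The label
   "tail-area FDR" (not local fdr) is recorded in run metadata; with 3v3
   designs all distinct splits are enumerated, larger designs sample
   `n_permutations` (default 1000) random reassignments from a seeded
   stream.
7. **Significance call.** |z_ratio| ≥ 1.5 (boundary inclusive), FDR ≤ 0.3,
   p < 0.05, and not excluded; direction is the sign of the Z-ratio. All
   thresholds configurable.

## Switch partition

A gene is **exclusive-translatome** when significant in TL and not in TR —
by default any TR significance eliminates it, regardless of direction
(a direction-matched mode is available). Genes failing detection in either
compartment are assigned to the null set and flagged rather than dropped.
The four sets are an asserted disjoint cover of the common gene universe;
swapping the TL and TR inputs swaps the exclusive sets exactly. Top tables
rank exclusive genes by |z_ratio| with p-value then gene-id tie-breaks.

## Motif enrichment

Sequences are 5′-UTRs with the TSS at position 0; the search window is
0-based half-open [0, 200) and a match counts when its start is inside the
window (it may extend past the end). Matching is exact with optional IUPAC
degeneracy, overlaps all counted; counting is gene-level (a gene counts
once however many sites it has). Over-representation of a motif in targets
vs universe is the hypergeometric tail P[X ≥ k] with enrichment factor
(k/n)/(K/N). Discovery enumerates the k-mers present in ≥ 2 target windows
(not all 4^k — statistically identical for ranking at desk scale) and
Bonferroni-adjusts over **every distinct k-mer observed in target windows**:
the ≥ 2-gene filter is a selection from that family, and correcting only
over its survivors understates the family-wise error (chance k-mer triples
would otherwise reach adjusted p < 0.05 in roughly a quarter of unplanted
runs). Diagnostics: Mann-Whitney tests for GC and length bias of targets vs
background, an exact binomial test (null 0.5) on sense vs
reverse-complement site counts for strand bias, and a KS test of match
starts against uniform on the window for localization (reported NA below 5
matches). PWM similarity to a reference (a built-in 5′TOP pyrimidine-tract
PWM is provided) is the maximal mean per-column Pearson correlation over
ungapped offsets with ≥ 4 overlapping columns; zero-variance columns
contribute 0.

## Polysome fractions

Per-fraction quantity is efficiency^(Ct_spike − Ct_target) with
amplification efficiency 2.0 by default (perfect doubling; configurable per
assay). Because the spike is added to each fraction's RNA, any per-fraction
recovery difference shifts both Cts equally and cancels — an invariance the
tests assert. Percentages are computed per replicate and then averaged,
matching per-experiment spike normalization, rather than pooling Cts.
Heavy-polysome share sums fractions {9, 10, 11} of an 11-fraction gradient
by default. Profile comparisons run per-fraction and heavy-share
equal-variance t-tests with degenerate-variance guards.

## Decay kinetics

First-order decay fitted by OLS of ln(abundance) on time (hours); rate
k = −slope, half-life ln 2 / k. A non-negative slope reports a "stable"
species with infinite half-life instead of failing. Replicates are pooled
into one regression by default (per-replicate fits by flag). Confidence
intervals are 2.5–97.5 percentiles over residual-resampling bootstrap
refits; when more than 2.5% of refits are non-decaying the upper bound is
infinite. Densitometry inputs are normalized as target/loading-control
ratios (optionally rescaled so t = 0 equals 1); qPCR relative expression
uses the delta-Ct convention fold = efficiency^(Ct_ref − Ct_target).

## Synthetic-data generators

The generators emulate the structure of a two-arm polysome-profiling study:
paired TL/TR matrices with 3 biological replicates per arm, gene baselines
uniform on log10 [1, 4], within-group Gaussian noise (default SD 0.1 on the
log10 scale — a plausible placeholder; real within-group variances are
design-specific), and per-observation detection p-values drawn uniform
(0, 0.02] for detected and (0.02, 1] for failed observations at a 2%
failure rate. Planted regulation classes {tl_only, tr_only, both, null}
default to 5% / 5% / 5% / 85%.

Two generator choices deserve explanation:

- **Class fractions.** The Z-ratio denominator is data-dependent, so the
  null-gene Z-ratio SD is approximately sqrt((1 − fE²)/(1 − f)) for
  regulated fraction f per compartment and effect size E. Small regulated
  fractions leave that SD near the 1.5 significance gate and make planted
  and null genes inseparable at E = 3 no matter the implementation; 5% per
  class puts the generator in the regime where planted classes are
  recoverable, consistent with translatome studies reporting regulation of
  a high percentage of genes.
- **Effect calibration.** Planted effects are additive log10 offsets whose
  size is calibrated once per generation so the realized mean |Z-ratio| of
  TL-regulated genes equals `effect_size`. The realized curve is
  non-monotone in the offset (very large offsets inflate the test columns'
  SD and dilute the per-column Z-scores), so calibration brackets the first
  upward crossing on a 31-point grid and refines it with Brent's method;
  targets beyond the curve's peak (Z-ratio saturation, ≈ 3.1 under the
  defaults) use the argmax offset as best effort.

UTR generation plants a motif at a uniform random start inside the window
with probability `plant_rate` into i.i.d. uniform-nucleotide sequences
(configurable GC). Fraction generation draws a monosome-peak + polysome-mass
mixture profile, moves `shift` of the total mass into the heavy fractions,
and encodes quantities as Ct pairs with per-fraction lognormal recovery
(cancelled by the spike) plus optional multiplicative quantity noise. Decay
courses are 2^(−t/half_life) with mean-one lognormal noise of coefficient
of variation `cv`; the default half-life parameter is 4.5 h, the reported
eIF4E1 protein half-life. Every generator is byte-reproducible given its
seed.

What the generators do **not** emulate: probe-level bead data, batch or
spatial array artifacts, correlated gene-gene structure, heteroscedastic
per-gene variances, UTR sequence composition of real genomes, or synthesis
plus-decay kinetics. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not performance on
real arrays.

## Problem sizes and numerical choices

Tests and the acceptance script run at 300–4000 genes, 3 replicates per
arm, 50 target / 500 background UTRs and ≤ 20 Monte-Carlo seeds per
property — sizes at which every DERIVED expectation is recomputable in
seconds while leaving the statistics in the regime the defaults target.
Degenerate inputs are guarded rather than fatal wherever a scientific
reading exists (identical groups → p = 1, zero FDR denominators → capped,
non-decaying fits → "stable"); configuration errors, malformed data and
unguardable numerics raise distinct exception families that the CLI maps
to exit codes 2/3/4.

## Known limitations

- The permutation FDR is conservative when planted effects leak into mixed
  2:1 label splits; with 3v3 designs only 9 informative splits exist, so
  FDR resolution below ~0.1 per threshold is smoothing-dependent.
- The Venn partition treats "concurrent change" as any-direction TR
  significance; direction-matched elimination is available but not default.
- Motif discovery scores exact k-mers only; degenerate/PWM refinement of
  discovered motifs is out of scope (the PWM comparison utility accepts
  externally built PWMs).
- Decay fitting assumes a single exponential; plateau or biphasic decay
  will show in r² and the bootstrap interval but is not modelled.
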