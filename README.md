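# transwitch

Analysis pipeline for **translational-switch** experiments: studies that ask
which mRNAs change in the *translatome* (polysome-bound mRNA from heavy
sucrose-gradient fractions) without a concurrent change in the
*transcriptome* (total mRNA). The package implements the complete
quantitative workflow of such a study — Z-ratio differential expression,
translatome-exclusive gene calling, 5′-UTR motif over-representation,
spike-in-normalized polysome-fraction quantification, and decay-kinetics
estimation — together with seeded synthetic-data generators that emulate
every input, so the whole pipeline is testable offline with planted ground
truth.

Intended users: computational biologists analysing polysome-profiling /
translatome microarray or qPCR experiments, and anyone who needs a tested,
reproducible implementation of the classic Z-ratio significance workflow.

## The statistics

**Z-ratio differential expression.** Each array (sample) is Z-score
normalized across detected genes, z = (x − μ_col)/σ_col (log10 intensities,
population SD). The per-gene effect statistic for a contrast is

```
z_ratio(g) = ( mean_z_test(g) − mean_z_ref(g) ) / SD_genes( mean-z differences )
```

A gene is significant when |z_ratio| ≥ 1.5, a two-tailed equal-variance
t-test on the per-sample Z-scores gives p < 0.05, and a label-permutation
empirical FDR ≤ 0.3 — after detection filtering (detection p ≤ 0.02) and
exclusion of genes with excessive within-group variance.

**Translatome-exclusive calling.** Genes significant in the translatome
contrast are eliminated if the transcriptome contrast also calls them,
yielding the Venn partition {exclusive-TL, exclusive-TR, shared, null}.

**5′-UTR motif enrichment.** 10-mers occurring within a [0, 200) bp window
of the TSS are scored for over-representation in a target gene set against
a gene universe with the hypergeometric tail P[X ≥ k] on gene-level counts,
Bonferroni-corrected over the searched k-mer family, with GC/length/strand/
localization bias diagnostics and PWM comparison to the 5′TOP motif.

**Polysome fractions.** Per-fraction transcript quantity is
efficiency^(Ct_spike − Ct_target) against a luciferase spike-in, expressed
as percent of the gradient total; the heavy-polysome share sums fractions
9–11 of the 11-fraction gradient.

**Decay kinetics.** Chase time courses are fit by OLS of ln(abundance) on
time; half-life = ln 2 / k with residual-bootstrap confidence intervals.

## Worked example

```
$ transwitch synth --seed 1 --out-dir inputs   # generate all synthetic inputs
$ transwitch run --seed 1 --out-dir demo       # full pipeline + manifest
```

The run directory contains per-contrast differential tables, the partition
and confusion matrix against planted truth, ranked motifs, fraction
comparisons, the decay fit, and `manifest.json` with every threshold, seed
and method decision. For seed 1 (2000 genes, 3 replicates per arm, planted
effect size 3) the confusion matrix is:

```
truth     exclusive_tl  exclusive_tr  null  shared
both                 7            11     1      78
null                 0             0  1714       0
tl_only             95             0     2       0
tr_only              0            85     7       0
```

i.e. 95 of 97 planted translatome-only genes are recovered into the
exclusive-translatome set and no pure-null gene leaks into it; the planted
10-mer `ATGCATGCAT` ranks first among discovered motifs (adjusted
p ≈ 8.5e-48), and the planted +15-percentage-point heavy-fraction shift is
recovered as +15.9 pp (t-test p ≈ 1.1e-07).

The same stages are importable as a library:

```python
from transwitch import GenConfig, gen_expression, run_contrast, partition
from transwitch.synthdata import default_contrasts

cfg = GenConfig(n_genes=2000, effect_size=3.0, seed=1)
study, truth = gen_expression(cfg)
tl_c, tr_c = default_contrasts(cfg)
part = partition(run_contrast(study, tl_c, seed=1).table,
                 run_contrast(study, tr_c, seed=1).table)
print(part.counts())
```

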