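# Methods

This note documents the models and statistics implemented in `tepnorm`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## Problem setting

Platelets take up and re-splice tumor-derived RNA ("tumor-educated
platelets"), which makes their transcriptome attractive for liquid
biopsy — and makes reference-gene choice for RT-qPCR non-obvious,
because genes that are stable internal controls in tissues need not be
stable in platelets across cancers. The pipeline has three stages:
shortlist candidate reference genes from bulk RNA-seq counts, rank the
shortlisted candidates by Ct-based stability algorithms, and apply the
winning reference gene in ΔΔCt quantification of a target gene.

## Shortlist cascade

Input is a genes × samples count matrix with one group label per sample
(`normal` vs. any number of tumor subtypes, pooled as `tumor`) and an
optional per-sample intron-spanning-read total used as a quality metric.

Stages, in order, with defaults:

| stage | rule | default |
|---|---|---|
| sample depth | drop samples with reads < `min_reads` (strict) | 400 000 |
| zero fraction | drop genes with zero counts in > `max_zero_frac` of samples (strict) | 0.70 |
| transform | log2CPM with pseudo-count: `log2(count/libsize·10⁶ + prior)` | prior = 1.0 |
| criterion 1 | both group-mean ratios < `fold_max`; non-positive means fail | 1.2 |
| criterion 2 | rank by group mean ≤ ceil(`top_frac`·G) in both groups | 0.10 |
| criterion 3 | CV = SD/mean < `cv_max` in both groups | 0.10 |
| refinement | mean > `mean_min` and CV < `cv_max_refine` in both groups | 1.0, 0.01 |
| intersection | keep candidates present in the known-reference list | shipped 73-gene list |

Conventions and choices:

- **Boundary semantics are strict inequalities** throughout: a sample at
  exactly the read threshold is retained, a gene at exactly the zero
  fraction is retained, a Ct of exactly 35 is excluded downstream.
- **Library size** is the column sum of the matrix after sample
  filtering (no external library-size source is assumed); CPM therefore
  uses post-sample-filter, pre-gene-filter library sizes.
- **Criteria 1–3 are conjunctive on one gene universe** (the
  post-zero-filter gene set), not sequentially re-ranked; the top-decile
  cut keeps all genes tied at the boundary rank (`method="min"`).
- **Criterion 1 operates on means of log2CPM** by default. Because
  fold-change criteria are sometimes stated on the linear scale, a
  config flag (`use_linear_means`) switches criterion 1 to linear-scale
  CPM means; ranking and CV always use log2CPM.
- **The refinement "CV < 1"** is read as CV < 1 percent (0.01): an
  absolute CV < 1 would be vacuous after criterion 3's CV < 10%. Both
  readings are runnable via `cv_max_refine`.
- **Gene-id normalization for the intersection**: trim, uppercase,
  strip Ensembl version suffixes. The shipped known-reference list is a
  curated, replaceable plain-text file of 73 widely used human
  housekeeping genes (`known_list_path` overrides it).
- CV is undefined (and the gene fails) wherever a group mean is ≤ 0.

Every stage logs genes entering/surviving/removed (`FilterReport`), so
the attrition table is available for any run, and relaxing any
threshold can only grow the surviving set (tested property).

## Stability algorithms

All four methods consume a collapsed Ct panel (one value per gene ×
sample) after the inclusion rule (Ct < 35 kept) and replicate averaging
(mean of surviving replicates; cells with fewer than `min_reps = 2`
survivors become missing). Amplification efficiency defaults to E = 2
(perfect doubling); log2 relative quantities are
`a(g,s) = (Ct_cal(g) − Ct(g,s))·log2(E)`, calibrated per gene to its
least-expressed sample so quantities are ≥ 1. The calibration constant
cancels in every downstream statistic.

- **Comparative ΔCt**: `S(i) = mean_{k≠i} SD_s(Ct_i − Ct_k)` with n−1
  SDs over pairwise-complete samples; a gene pair sharing fewer than 3
  samples is an error (or the pair is dropped, per config).
- **geNorm**: `V(i,k) = SD_s(a_i − a_k)`, `M(i) = mean_{k≠i} V(i,k)` on
  complete cases; the gene with the largest M is removed iteratively
  until two remain (ties removed lexicographically last, so runs are
  deterministic). Ranks: reverse removal order; the final pair shares
  rank 1.5, because the aggregation must consume a number for a joint
  first place. Normalization factors `NF_n(s)` are geometric means of
  the top-n genes' relative quantities, and
  `V(n/n+1) = SD_s(log2(NF_n/NF_{n+1}))` is reported for n = 2…k−1
  without a "how many genes" decision rule. With E = 2 the first-step
  M values coincide exactly with the comparative ΔCt statistic (tested
  to 1e-12).
- **NormFinder-style estimator**: sample-center across genes,
  `x(g,s) = a(g,s) − mean_g a(·,s)`; per group compute mean `m(g,γ)`
  and variance `v(g,γ)` (n−1); the group bias `d(g,γ) = m(g,γ) − m(g)`
  is shrunk as `d̃² = max(d² − v/n_γ, 0)` to avoid negative bias
  estimates; the stability value is
  `ρ(g) = Σ_γ (n_γ/N)(√d̃² + √(v/n_γ))`. With a single group the
  estimator falls back to the SD of the centered values. This is a
  transparent re-derivation in the spirit of the model-based original;
  fidelity to the published estimator is approximate by construction.
- **BestKeeper**: descriptors on the **raw Ct scale** — n, geometric
  and arithmetic mean, min, max, "SD" as the mean absolute deviation
  around the arithmetic mean (the original tool's descriptive
  convention; classic n−1 SD behind `classic_sd`), CV% = 100·MAD/mean.
  Genes with SD > 1 cycle are flagged inconsistent. The BestKeeper
  index is the per-sample geometric mean Ct over genes (complete
  cases); per-gene Pearson r (and two-sided p) against the index is
  reported. Ranking for aggregation is by ascending MAD; r is reported
  but not used for ranking, since the literature states no explicit
  rule.
- **Aggregation**: the comprehensive score is the geometric mean of the
  per-method ranks; ascending score gives the comprehensive rank, ties
  broken alphabetically so the output is a strict permutation. No
  partial aggregation: every method must rank every gene.

Missing data: ΔCt uses pairwise-complete samples; geNorm, NormFinder
and BestKeeper's index use complete cases after dropping samples
missing any retained gene. A `drop_gene_first` switch first drops genes
missing in more than half the samples, for panels where one bad gene
would otherwise eliminate most samples.

Invariances (all tested): adding a constant to one sample's Cts (a
loading effect) leaves ΔCt, geNorm and NormFinder outputs unchanged and
changes BestKeeper's descriptors, which is the intended contrast
between the ΔCt family and raw-scale descriptors; adding a constant to
one gene's Cts (calibration) leaves all three invariant.

## ΔΔCt application

`ΔCt(s) = Ct_target(s) − Ct_reference(s)`; fold change
`2^−(ΔCt(s) − mean ΔCt_control)`, so control fold changes have
geometric mean 1 by construction. The group comparison is a two-sided
equal-variance Student's t-test on ΔCt (Welch behind a flag), applied
on the ΔCt scale where normality is plausible rather than on fold
changes. Samples missing the reference gene are dropped with a warning;
a panel with zero variance in both groups is reported as a degenerate,
non-significant case (t = 0, p undefined) rather than an error.

## Synthetic-data generator

**Counts.** Negative-binomial draws (the standard overdispersed RNA-seq
model) with log-normal library sizes (median 10⁶, σ = 0.25 on the log
scale), 50 + 50 samples and 500 genes by default. Gene roles partition
the panel and are placed strictly on the far sides of every threshold
so that cascade recovery is a sharp test:

- *housekeeping* (2%): base mean log2CPM in 11–12 (top decile), no
  group effect, near-Poisson dispersion (size 10⁴) — empirical group CV
  well under 1%;
- *shifted* (30%): base mean in 2–10; one randomly chosen group's mean
  lowered by 35%, putting the mean ratio at ~1.54 (beyond the 1.2
  criterion) while keeping both group means below the housekeeping
  band, so criterion 2 stays discriminative;
- *noisy* (30%): base mean in 2–10, dispersion size 0.4 — group CV far
  above 10%;
- *low* (remainder): mean count 0.01–0.2 — zero fraction above 70%.

The per-sample intron-spanning-read metadata is the true library size.
Note that realized log2CPM differs from the nominal base mean by a
global composition offset (the simulated genes are a 500-gene subset,
not a whole transcriptome); all cascade criteria are relative (ratios,
ranks, CVs), so the offset is immaterial, and the generator's moments
are verified on the linear CPM scale against the true library sizes,
where the negative-binomial mean is exact. That coverage check uses a
two-standard-error band at its correct ~95% coverage with a binomial
tolerance (α ≈ 10⁻³) so the test's false-failure rate is controlled.

**Ct panels.** Additive normal model,
`Ct(g,s,rep) = baseline(g) + shift(g, group(s)) + b(s) + ε`, with the
shared loading effect `b(s) ~ N(0, 0.5²)` — exactly the nuisance the
ΔCt family cancels — replicate noise `ε ~ N(0, noise_sd(g)²)`, three
replicates, and missingness completely at random (default rate 0;
informative dropout is out of scope). The default stability panel
mirrors a five-group validation cohort (one healthy + four tumor
groups, six subjects each): one planted stable gene (no shift,
0.1-cycle noise) among three group-shifted genes (≥ 1 cycle, 0.3-cycle
noise) and three noisy genes (0.8–1.2-cycle noise). The validation
panel mirrors a 21 + 21 case/control design with a −1.5-cycle planted
shift and 0.5-cycle noise.

What passing these tests shows — and does not. The generator reproduces
the statistical structure the methods assume (NB counts, additive Ct
model with shared loading effects, MCAR missingness). It does not
simulate read-level artifacts, platelet splicing dynamics, batch
structure, primer-efficiency variation or informative dropout, so
planted-truth recovery demonstrates correctness of the algorithms under
their assumed model, not performance on real cohorts.

## Problem sizes and determinism

Simulation sizes used by the tests and the acceptance script — 100
random 5 × 8 panels for oracle equivalence, 200 seven-gene panels for
stability recovery, one 500 × 100 matrix for cascade recovery, 100
replicates for validation power — are the package's chosen balance
between statistical resolution and quick, deterministic runs; every
random draw flows from a single integer seed via spawned
`SeedSequence`s. Per-method rank ties use average ranks; the geNorm
elimination tie-break (lexicographically last) and the alphabetical
aggregate tie-break make all outputs deterministic.

## Known limitations

- The NormFinder-style estimator is a faithful re-derivation of the
  bias/variance decomposition, not a port of the original software;
  small numerical differences from the original are expected.
- BestKeeper's correlation against an index that itself contains the
  gene induces a positive dependence, as in the original tool; r is
  reported for inspection, not used for ranking.
- The shortlist cascade's absolute candidate counts on real data depend
  on preprocessing choices (pseudo-count, which samples enter the
  library sizes) that published workflows often leave open; every
  threshold is exposed in config for sensitivity analysis, and the
  attrition table makes stage-wise effects visible.
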