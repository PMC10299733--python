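# Methods

## Problem setting

Two neuroendocrine tumor cohorts — PANNET (pancreatic neuroendocrine
tumors) and PGL (pheochromocytoma/paraganglioma) — share similar
gene-expression profiles but differ in miRNA expression. The pipeline
identifies the miRNAs that separate them, under a severe imbalance (7 vs
149 primary samples) and with demographic composition differences (gender,
race, ethnicity) that could confound a single pooled analysis. All
expression values are on the log2(RPM+1) scale (reads per million, with
pseudocount).

## Characteristic-direction ranking

The discriminative statistic is a single multivariate L2-penalized logistic
regression of cohort membership on all standardized miRNA features:

    minimize  sum_i w_i log(1 + exp(-z_i (b0 + x_i' b))) + (ridge/2) ||b||^2

with z_i ∈ {−1, +1}, the intercept b0 unpenalized, and optional
inverse-frequency sample weights w_i (off by default; the pipeline
addresses imbalance by stratified re-analysis, not re-weighting). The
unit-normalized coefficient vector b/‖b‖ is the characteristic direction;
features are ranked by |b_j|, ties broken lexicographically by feature id
so rankings are deterministic. A positive coefficient means the feature is
elevated in the positively oriented group (the first-named group by
default).

Choices that matter:

- **Standardization** (mean 0, sd 1 per feature) precedes the fit so
  coefficient magnitudes are comparable across features; zero-variance
  features are centered and flagged.
- **Ridge strength** defaults to 1.0 on standardized features. Any
  positive value makes the problem strictly convex and well-posed at
  p = 294 > n = 7; the ranking is insensitive to the exact value over a
  wide range because the planted separations are large. As ridge → ∞ the
  direction provably converges to the standardized group-mean-difference
  direction (the first-order expansion of the gradient at b = 0), which is
  verified in the test suite.
- **Solver**: damped Newton (IRLS) with Armijo step halving on the exact
  penalized objective; the Hessian X'WX + ridge·I is positive definite, so
  convergence is global. Stopping rule: gradient infinity-norm < 1e-10 or
  100 iterations. The fit is solved in a canonical label orientation
  (lexicographically smaller class positive) and re-signed, which makes
  label-swap antisymmetry bit-exact rather than merely approximate.
- One multivariate fit is used (all features jointly), not per-feature
  fits: the coefficient of each miRNA is then its contribution conditional
  on the others, which is what a "direction in expression space" means.
  This is recorded in the report provenance.

## Stratified consensus selection

Five strata are built from the clinical table after the primary-tumor
filter (barcode sample-type suffix "01"): all primaries, males, females,
race "white", ethnicity "not hispanic or latino". Strata are predicates
over clinical fields only; each stratum is a subset of the all-primary
stratum. The ethnicity stratum requires the exact category, so a sample
with unclassified ethnicity is excluded from it (strict predicate reading;
the exclusion is visible in the stratum sizes). A stratum where either
cohort has fewer than two samples cannot support the ranking or ANOVA and
is skipped with a warning; the run degrades to the usable strata and
records which were used.

The ranking runs independently in each usable stratum; a feature is
selected when it appears in the top k (default k = 8, configurable) of
**every** usable stratum. Strict intersection is the default because it is
the most conservative reading of "repeatedly found among the top positions
in all lists"; a `min_lists` parameter relaxes it to a frequency threshold.
Selected markers are ordered by mean rank across strata.

Each selected marker is confirmed by one-way ANOVA between the two cohorts
on the all-primary stratum (a single pooled mean ± sd per cohort is the
natural reporting unit there). For two groups F = t² (pooled-variance
t-test), which the suite verifies on random instances against a direct
sum-of-squares oracle. Raw p-values are reported, with
Benjamini–Hochberg-adjusted values in an adjacent column. Degenerate
inputs: zero within-group variance in both groups with equal means yields
an undefined F, reported as NaN with an explanatory note (never silently
dropped); with unequal means F = ∞, p = 0.

## Morphing projections

Each feature view (gene block, miRNA block) is embedded separately with
t-SNE (Euclidean metric on optionally standardized log2 values, the
community default; exact method, fixed seed mandatory — there is no hidden
global RNG state). Perplexity defaults to 30 and is automatically lowered
to just under (n − 1)/3 for small cohorts; an explicitly requested
perplexity that violates the bound is an error naming the bound.

Because independent t-SNE runs differ by arbitrary rotation/reflection and
scale, the second view is aligned to the first by full orthogonal
Procrustes (rotation/reflection + isotropic scale + translation, minimizing
summed squared distance) before blending. A morph frame at weight
w ∈ [0, 1] is the per-sample convex combination of the aligned coordinate
pairs, so trajectories are linear and endpoint-exact. Whether the original
visualization tool blends projection axes before embedding or blends final
coordinates is not determinable from its description; coordinate blending
of aligned embeddings is implemented and documented as the interpretation.

## Synthetic cohort generator

The generator defines the study conditions and is first-class, tested code:

- 294 miRNA features; 7 PANNET and 149 PGL primary samples, plus three
  non-primary PGL samples (sample-type codes "06", "06", "11") that the
  primary filter removes — exercising the filter while keeping the
  analysis set at exactly 7 vs 149.
- Six planted marker profiles drawn per cohort from Gaussians with the
  published per-cohort mean ± sd (log2(RPM+1) scale): miR-141-3p
  (10.7 ± 0.76 / 1.66 ± 0.87 PANNET/PGL), miR-200c-3p (13.4 ± 0.80 /
  4.33 ± 1.09), miR-10b-5p (13.4 ± 1.0 / 17.8 ± 0.50), miR-192-5p
  (13.7 ± 0.6 / 8.78 ± 0.87), miR-194-5p (12.4 ± 0.72 / 7.65 ± 0.86),
  miR-10b-3p (2.65 ± 0.96 / 6.17 ± 0.65). Every planted separation
  exceeds 3.5 pooled-sd units, which is what makes near-certain recovery
  the correct expectation.
- All remaining features are nulls sharing one background Gaussian in both
  cohorts, N(7.0, 1.5²) — a typical mid-range log2(RPM+1) level chosen
  once; the planted effect sizes do not depend on it. Nulls make
  specificity testable.
- Gaussian noise on the log2 scale (group summaries are reported as
  mean ± sd on that scale and the observed violin shapes are unimodal; no
  heavier-tailed model is indicated). Values are clipped at 0 since
  log2(RPM+1) ≥ 0. The clip truncates the lower tail of profiles whose
  mean sits within ~2 sd of zero: for the 1.66 ± 0.87 profile it biases
  the sd by about −1.5%, negligible elsewhere. A `clip_at_zero` toggle
  exposes the raw sampler; moment-fidelity tests check the raw sampler at
  1% and bound the clipped bias separately.
- Covariates: PGL 64 male / 85 female among primaries; PANNET all white,
  6 of 7 not-hispanic-or-latino (1 unclassified); PANNET gender is not
  published and defaults to 3 male / 4 female so both gender strata retain
  ≥ 2 PANNET samples. PGL race/ethnicity margins (135/9/5 white/black/
  asian; 140/9 not-hispanic/hispanic) are chosen once to reflect a
  mostly-white, mostly-non-hispanic cohort. Categories are assigned as
  exact counts (largest remainder from the configured frequencies) and
  randomly permuted across samples: this reproduces the published
  composition exactly in every replicate and guarantees all five strata
  are usable, which i.i.d. category sampling cannot at n = 7.
- `permute_labels` provides the matched null model (labels shuffled,
  group sizes preserved, expression untouched).

What the generator does **not** emulate: inter-miRNA correlation (features
are independent; real miRNA families are strongly co-expressed), read-count
noise, batch effects, or outlier samples. Passing tests therefore
demonstrate that the pipeline recovers planted effects of the published
magnitude under idealized noise — not that it would behave identically on
real sequencing data, where correlated features can share or split ranking
credit.

## Percentile normalization

Independently processed datasets are made comparable by mapping each
measurement to its percentile within its own dataset's pooled value
distribution: with midrank handling of ties, value = (rank − 0.5)/N over
all N cells of the dataset (default), or within each feature row
(`pool="per_feature"`). The global pool is the default because the
reference distribution is "the full expression levels across all samples
in the dataset"; the per-feature variant is provided since the global pool
makes between-feature level differences part of the signal. The midrank
convention keeps values strictly inside (0, 1) (mean exactly 0.5 without
ties) and makes the all-equal case well-defined (all 0.5).

The formal property justifying cross-platform use: percentiles depend only
on the within-dataset ordering, so any strictly increasing per-dataset
transform of raw values (a platform or normalization change) leaves every
downstream comparison identical. This is tested exhaustively on small
matrices and by property tests.

Cross-dataset validation normalizes each dataset separately (never pooled),
then contrasts the cohorts on the concatenated percentile values, keeping
per-dataset group medians/IQRs for reporting. The group test on percentiles
is one-way ANOVA by default — consistent with the discovery stage — with a
Wilcoxon rank-sum alternative behind a flag, since the original choice of
test for the percentile-scale comparison is not stated; the test used is
recorded in every comparison record.

## Problem sizes and determinism

The acceptance script and test suite run the full pipeline at the study
scale (294 × 159, five strata): 50 replicate cohorts for consensus
recovery, 50 label permutations for specificity, 200 replicates for
generator/summary fidelity — sizes at which the Monte Carlo error of every
checked quantity is far below its tolerance while a full run stays in the
tens of seconds. Every stochastic step (generation, permutation, t-SNE)
takes an explicit seed; replicate seeds are spawned from a single root via
`numpy.random.SeedSequence`.

## Known limitations

- Independence of features in the generator (see above): consensus
  sensitivity/specificity results transfer to real data only qualitatively.
- The characteristic direction is a single global linear discriminant;
  markers whose effect is conditional (e.g. present only in one gender)
  would be diluted — the stratified re-analysis mitigates but does not
  remove this.
- ANOVA on percentile values is a test on ranks wearing a parametric coat;
  it is reported alongside the rank-sum test rather than defended as
  optimal.
- k = 8 is a configuration default, not an inferred quantity; no automatic
  selection of k is attempted.
- No survival/stage analysis and no GEO series-matrix parsing: readers
  accept the TSV dialects, and validation datasets are emulated
  synthetically.
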