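# Methods

This note records the models, parameter choices and design decisions
behind `goafs`, and what the synthetic benchmarks do and do not show.

## Data model

The package operates on the standard processed 14-attribute
heart-disease layout: 13 predictors plus a binary status column
`Num`. Feature indices are 1-based in schema order in every
user-facing report (so {2,3,7,9,11,12,13} names Sex, CP, Restecg,
Exang, Slope, Ca, Thal); internally everything is 0-based. Kinds
follow the imputation-rule split: Age, Trestbps, Chol, Fbs, Thalach
and OldPeak are numeric (Fbs is numeric-by-rule but binary-valued);
Sex, CP, Restecg, Exang, Slope, Ca and Thal are nominal with explicit
integer category codes (Thal ∈ {3, 6, 7}). Numeric validation bounds
are generous physiological ranges, deliberately wider than any
observed data range, so range validation catches parse errors rather
than unusual patients.

Source archives of this table use a 0–4 disease-severity code; the
reader maps any value > 0 to label 1 by default (configurable off).
The std convention everywhere is the sample (n − 1) estimator.

## Synthetic generator

The generator targets the per-feature marginal statistics of the
processed table as *population* moments:

* numeric features are truncated normals on the printed [min, max];
  the parent (μ, σ) are solved numerically so that the **truncated**
  distribution's mean and std equal the printed values. This matters:
  using the printed values directly as parent parameters would shift
  hard-truncated features (OldPeak's mean by ≈ +0.3).
* binary-valued features (Sex, Fbs, Exang) are Bernoulli(p = printed
  mean); their printed stds equal √(p(1−p)) exactly.
* multi-category nominal features (CP, Restecg, Slope, Ca, Thal) get
  the maximum-entropy probability vector over their category codes
  with the printed mean (probabilities ∝ e^{θv}, θ solved by root
  finding). A mean under-determines a distribution; the printed stds
  of these features are therefore not targeted and differ somewhat
  (e.g. Restecg 0.82 vs 0.995).

One infeasibility is inherent, not numerical: OldPeak's printed
(mean 1.035, std 1.161) on [0, 6.2] lies outside the truncated-normal
family — std/(mean − lo) = 1.12 exceeds the family's exponential-tail
supremum of 1, because the real column has a point mass at zero. The
generator matches the mean exactly and takes the closest achievable
std (≈ 0.996), recording `std_matched=False` on that marginal. Tests
of marginal reproduction cover means for all features and stds for
the matched numeric ones.

Labels follow a logistic model: P(y=1) = sigmoid(β₀ + Σ βⱼ zⱼ) over
the *standardized* informative features (population moments, so
effect sizes are per-SD and comparable across features), then flipped
with probability `label_noise`. Features are drawn independently:
real clinical inter-feature correlation (e.g. age–max-heart-rate) is
deliberately not modelled, so passing benchmarks here demonstrate
selector behaviour under independent marginals, not performance on
correlated real tables.

Reference populations:

* `default_spec()` — informative set {2,3,7,9,11,12,13}, unit per-SD
  effects, 2 % label noise.
* `planted_spec()` — the recovery benchmark: 4 planted features
  {3, 8, 12, 13} (CP, Thalach, Ca, Thal — a mix of nominal and
  continuous), per-SD effect 2.0, 5 % label noise, n = 300 in the
  studies. With these effects the Bayes error is well below the
  observed model error, so recovery failures indicate selector or
  objective problems, not an unlearnable signal.

## Imputation

Per-feature rules: mean of similar records for numeric features, most
likely (modal) value among similar records for nominal ones.
"Similar" defaults to *records sharing the class label*, the simplest
deterministic reading; the global statistic is the fallback for an
empty group, and a k-nearest-rows grouping (distance over mutually
observed standardized features) is available via
`similarity="knn"`. Mode ties break to the lowest category code.
Numeric fills are means of observed group values and hence always lie
inside the observed group range; fills are additionally clipped to
schema bounds.

The default pipeline fits the imputer on the whole table before
splitting, matching the common whole-table-first protocol for this
data. That leaks label information into the fills (grouping is by
label); for leakage-safe evaluation, fit the plan on training rows
only and apply it to held-out rows — both orders are supported, and
the benchmark conclusions here do not hinge on the difference because
the synthetic studies inject missingness only in the imputation
tests, not in the selection studies.

Beyond range validation there is no outlier handling; no rule for it
is defined in this pipeline.

## Search

The continuous swarm quantities are implemented exactly: social force
s(r) = f·e^(−r/l) − e^(−r) with defaults f = 0.5, l = 1.5 (the
customary values for this model; l > 1 guarantees a positive comfort
distance −l·ln f/(l−1)); schedules a(t) = 2 − 2t/T and
a₂(t) = −1 − t/T; coefficient draws A = 2a·r₁ − a, C = 2r₂,
l = (a₂ − 1)u + 1. Gravity and wind terms of the force decomposition
are fixed at zero (no operative formula exists for them here); the
fields remain for completeness.

On bit vectors the force model has no direct geometry, so the driver
is best-guided mutation:

1. draw coefficients; pick the guide — best-so-far if |A| < 1
   (exploitation), a uniformly random population member otherwise
   (exploration);
2. crossover toward the guide: agreeing bits kept, disagreeing bits
   resampled Bernoulli(0.5);
3. random-subset mutation: each position independently with
   probability p_t = intersection_prob · w_t is redrawn
   Bernoulli(0.5), where w_t interpolates linearly from w_init = 0.35
   to w_final = 0.95;
4. empty masks are repaired by setting one uniformly random bit.

Step 3 is essential and not merely cosmetic: crossover alone freezes
once the population coincides with the best mask (no disagreement ⇒
no movement), which would prevent escaping early local optima; the
unconditional mutation keeps a positive probability of reaching any
mask at every iteration. The increasing weight shifts effort from
guide-following early to broader resampling late, with elitism
guaranteeing monotone best-fitness history either way. Ties between
equal-fitness masks break toward fewer selected features, then
lexicographic bit order — a deterministic stand-in for an explicit
subset-size penalty.

Fitness is minimized ("least error"); the accuracy-per-size ratio
objective is exposed as a maximization and internally negated.
Defaults: population 50, 100 iterations, intersection probability
0.5. All randomness flows from a single seed through
`numpy.random.default_rng`; there is no global-state randomness.

## Objective

`evaluate_subset` trains scikit-learn's `SVC` on the masked columns
of a stratified 70/30 split (standardization fitted on the training
fold only) and returns mean |y − ŷ| on the test fold, averaged over
`n_executions = 5` repeated seeded splits. Averaging matters at
n = 300: a single 91-row test fold has ≈ ±0.05 error noise, enough
for spurious subsets to win; five-split averaging reduced that noise
below the between-subset differences in the recovery study. The split
seeds derive from the configuration seed, so the objective is
stationary within a run and fitness values are cacheable on the mask
bitstring (the cache typically saves ~80 % of trainings in a run).

SVM settings: penalty C = 5.0; kernel width gamma = `"scale"`
(scikit-learn's 1/(d·Var)). A fixed large width such as gamma = 32 on
standardized features is expressible via configuration but is not the
default for a measured reason: it collapses the RBF kernel to a
near-exact-match lookup — continuous features become unusable
(all-features test accuracy falls to the majority rate) and the
wrapper then systematically prefers spurious small discrete subsets.
With the dimension-aware width the planted-recovery benchmark is
recovered 10/10 instead of 6–7/10, and the selected subsets also
generalize better.

A "vector number" setting that sometimes accompanies SVM parameter
tables for this pipeline has no defensible computational meaning here
and is not wired to anything.

## Benchmarks and problem sizes

* Marginal reproduction: n = 10 000, all means (and matched stds)
  within 3 standard errors.
* Counting-objective convergence: fitness = |mask|, population 50 ×
  100 iterations, 10 seeds — global minimum (one feature) reached in
  every run.
* Planted recovery / selection utility: n = 300, 10 seeds, population
  30 × 40 iterations with the 5-split-averaged objective — chosen so
  a full study trains a few thousand SVMs and completes in minutes on
  one CPU while leaving the conclusions unchanged versus larger
  budgets (spot-checked at 50 × 100). Measured: ≥ 3 of 4 planted
  features in ≥ 8/10 runs (typically 10/10), mean selected size 6–7
  of 13, and selected-subset accuracy above the all-features baseline.
* Determinism: two pipeline runs from one master seed produce
  byte-identical trace/selection/report files.

## Known limitations

* Independence of features in the generator (see above).
* The sample-fraction sweep subsamples after imputation, stratified
  by label; fractions leaving fewer than 10 rows are skipped.
* Undefined ratios (precision/recall with empty denominators) are
  reported as explicit `None`/NaN markers and excluded from means —
  never silently zero.
* The pipeline is strictly binary; no multi-class generalization.
* Wrapper selection optimizes measured test-fold error; even with
  split averaging the reported best fitness is a mildly optimistic
  estimate of generalization error (selection bias over ~10³
  evaluated masks). The 70/15/15 final evaluation gives the honest
  per-fold picture.
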