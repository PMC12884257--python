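# Methods

## The statistical problem

Two groups (patients, controls) are compared on region-of-interest
morphometry — cortical thickness (mm), surface area (mm²) and volume
(mm³) per region — plus clinical covariates and questionnaire totals.
Sample sizes are small (tens per group), questionnaire scores are
integer-valued and heavily tied, and thickness and area within a region
are dependent. The package therefore leans on rank and permutation
methods throughout, and treats the Fisher-method non-parametric
combination (NPC) of thickness and area as the primary regional test.

## Permutation test

For a region × metric the test statistic is the Mann–Whitney U of the
patient group (mean difference available as an option). Group labels
are shuffled uniformly; because U depends only on which pooled midranks
fall in the first group, ranks are computed once and each shuffle is an
O(n₁) rank sum. Two-sided extremeness is distance from the statistic's
null centre (n₁n₂/2 for U, 0 for the mean difference), both statistics
being symmetric about their centre under exchangeability. Empirical
p-values use the add-one convention p = (1 + #{|dev_b| ≥ |dev_obs|})/(B + 1),
which is valid (conservative) and never zero, so Fisher's −2·ln p is
always defined. For n₁ + n₂ ≤ 12 (configurable) all C(n₁+n₂, n₁)
relabelings are enumerated instead and p is exact without smoothing —
the observed labeling is itself one of the relabelings.

## Non-parametric combination

One set of shuffles is drawn per region and applied to *every* metric
(synchronized permutations), preserving the cross-metric dependence
that motivates NPC. For each metric the permuted statistics are
converted to within-permutation p-values by ranking each |dev_b|
against the full B-vector of its own metric (add-one convention); the
combining statistic T_b = −2 Σ_m ln p_{b,m} then has its own permutation
distribution, and the joint p is the add-one rank of T_obs within it.
Whether to synchronize the shuffles is a genuine design choice; we
synchronize because independent shuffles would destroy exactly the
dependence the joint test is meant to respect. FDR (Benjamini–Hochberg)
runs within metric across regions for the per-metric tests and across
regions for the joint tests; each printed table is one FDR family.

## Classical comparisons and effect sizes

Clinical variables use a gated test choice recorded in a `GateReport`:
Shapiro–Wilk per group (either p < 0.05 → Mann–Whitney U), then Levene
(mean-centred; p < 0.05 → Welch, else pooled t). Effect sizes are
Cohen's d (pooled SD, (n−1) weights) for mean tests and r = Z/√N for
rank tests. Two deliberate conventions:

* `effect_size_r` converts a *summary* U with the untied variance
  n₁n₂(n₁+n₂+1)/12 — printed U values carry no tie structure, so the
  untied formula is the only reproducible conversion. The raw-data path
  uses the tie-corrected variance.
* The raw-data Mann–Whitney asymptotic p applies a continuity
  correction; enumeration at n = 8/8 shows the corrected approximation
  stays within 0.01 of the exact two-sided p where the uncorrected one
  deviates by up to 0.046. The reported z stays uncorrected, matching
  the r = Z/√N convention. Exact p is used for min(n) ≤ 8 without ties.

Direction is first-argument-minus-second everywhere; report tables
state the group order.

## Associations and BMI-SDS

Kendall tau-b (tie corrections in both margins) is the screen
correlation, appropriate for tied Likert totals; p-values are exact for
n ≤ 10 without ties, else the tie-corrected normal approximation. The
screen's FDR family is the set of unique off-diagonal pairs of one
table. BMI-SDS uses the LMS method, z = ((BMI/M)^L − 1)/(L·S) with
L, M, S linearly interpolated at the subject's age within their sex
stratum; no extrapolation outside the grid. National growth references
are licensed, so the package reads any user TSV (`sex age L M S`) and
bundles only a synthetic reference (smooth logistic median rise from
~15.5 to ~21.5 kg/m² over ages 5–20, CV 10–13%, mild left skew) that is
labelled synthetic everywhere it appears.

## Regression

OLS via the classical covariance; standardized beta = B·sd(x)/sd(y)
with (n−1)-denominator SDs; 95% CI of B at the t critical value with
n−p−1 df; VIF_j = 1/(1 − R²_j) from auxiliary regressions. Backward
elimination removes the largest-p predictor while it exceeds
POUT = 0.10 and stops otherwise; ties break toward larger p then column
order; the removal trace is recorded. PIN = 0.05 is kept in the
interface for parity with the originating statistics package but pure
backward never re-enters a predictor; an optional re-entry flag
re-admits a removed predictor whose add-back p would fall below PIN.

## Power

`mc_power` draws Gaussian groups separated by d pooled SDs, runs the
B-permutation U test, and reports the rejection rate at α with binomial
SE. The data-generating model for power is a genuine unknown in this
kind of study; parametric Gaussian simulation from group summaries is
the default because it is the only choice fully determined by reported
numbers. The analytic minimum detectable effect size uses the
two-sample normal approximation d = (z_{1−α/2} + z_{power})·√(1/n₁+1/n₂)
(≈ 0.79 at n = 26/24, α = 0.05, 80% power); the optional noncentral-t
solver returns a slightly larger value (≈ 0.81) because it accounts for
the estimated variance. Note the simulated power of the *U* test at
d = MDES sits a little below 80% (≈ 0.77–0.78): the rank test pays the
Pitman efficiency (≈ 0.955) relative to the t-test under normality, and
the discrete add-one empirical p is slightly conservative.

## Synthetic cohort generator

The generator emulates the structure the analyses assume, not any real
dataset:

* **Groups:** 26 patients / 24 controls by default, all female, ages
  ~N(15.1, 1.6²) clipped to 12–19.
* **Morphometry:** per region, thickness and area deviations are
  bivariate standard normal with correlation ρ (default 0.3); volume is
  an independent draw. Values are mean + sd·(z + d·1{patient}) in
  native units, so the injected d is exactly the standardized group
  difference. Hemisphere tables add a small antisymmetric perturbation
  (5% of the region SD) such that averaging (thickness/area) or summing
  (volume) recovers the combined value.
* **Questionnaires:** a single latent severity factor, N(0,1) in
  controls and shifted by 2.0 SD in patients, drives every instrument
  through loadings (default 0.8): score = centre + scale·(λη + √(1−λ²)ε),
  rounded to integers and clipped to the instrument range — reproducing
  both the positive inter-questionnaire tau block and the ties that
  exercise tie-corrected statistics. With λ = 0.8 and shift 2.0 the
  induced standardized difference is ≈ 1.6, the magnitude seen for
  eating-disorder totals in adolescent patient/control comparisons.
* **BMI-SDS:** loaded −0.7 on severity (patients ≈ −1.4 SDS on
  average); raw BMI is recovered through the inverse LMS transform of
  the synthetic reference, so recomputing SDS from BMI round-trips.
* **Focal effect:** the default injects d = −1.1 into precuneus
  thickness only — the magnitude implied by a rank effect size of
  r ≈ −0.5 at these group sizes — leaving every other region × metric
  null.
* **Determinism:** one global seed; each table (region, questionnaire,
  aseg structure) draws from its own stream keyed by a stable hash of
  the table name, so adding a region leaves all other draws unchanged.

What the generator does *not* emulate: measurement noise correlated
across regions, non-Gaussian morphometry tails, missing data,
longitudinal structure, or scanner/site effects. Passing tests
therefore demonstrate the statistical machinery's calibration and
power under the assumed location-shift model, not robustness to those
real-data complications.

## Numerical choices and problem sizes

* Permutation comparisons use a tolerance of 1e−12 when counting
  "as-or-more-extreme" to make ties in floating-point deviations
  inclusive.
* Default B = 5000 for reported analyses; power simulations default to
  600 simulated datasets × 1200 permutations; the calibration checks in
  the test suite use 600 × 500 (type-I) and 600 × 1200 (power at the
  MDES), with smaller B in unit tests where only determinism or shape
  is at stake.
* Degenerate inputs: constant pooled data → p = 1, z = 0; both-group
  zero variance with unequal means is an error; perfect collinearity →
  infinite VIF flag; constant variables are skipped per-pair in
  correlation matrices.
* Seeds below 2³¹ are derived from the run seed via `SeedSequence`
  spawning.

## Known limitations

* The NPC implementation combines with Fisher's method only; Stouffer
  and Tippett combiners are out of scope.
* Group comparisons are unadjusted (no covariates); the regression
  stage is the only covariate model.
* ICV normalization is available but off by default — reported global
  volume fractions in the literature rarely state their denominator.
* The exhaustive permutation mode is limited to n₁ + n₂ ≤ 12 by
  combinatorial growth.
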