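# Methods

This note documents the models, defaults and numerical choices behind
`dietscore`, and what the synthetic-data tests do and do not establish.

## Scoring model

**GDQS.** The score is defined entirely by a configuration table: 25 food
groups, each with strictly increasing gram/day cut-offs delimiting
consumption categories (left-closed, right-open: a gram amount exactly at a
cut-off falls in the *upper* category, making boundary assignment
deterministic) and one non-negative point value per category. Roles
constrain the point shapes: the 16 *healthy* groups have non-decreasing
points (more intake never scores less), the 7 *unhealthy* groups
non-increasing points with the maximum at the zero-intake category, and the
2 *unhealthy-in-excessive-amounts* groups (red meat, high-fat dairy)
unimodal points that rise to a peak at moderate intake and fall below it at
high intake. GDQS+ sums healthy-group points (maximum 32), GDQS− the
unhealthy and excess groups' points (maximum 17), GDQS their sum (maximum
49). A consequence of genuine unimodality worth noting: an *empty* diet
does not reach the GDQS− maximum, because the excess groups award their
peak points at moderate, not zero, intake (the packaged table gives an
all-zero day GDQS− = 16 of 17).

Published sources for the score do not fix a single canonical cut-off/point
table, so the packaged table is an explicitly illustrative default with
field-plausible values; every structural claim the package makes (group
counts 25/16/7/2, maxima 49/32/17, risk boundaries) is *verified against
the loaded table by exhaustive per-category enumeration*, never assumed.
Scores are treated as real-valued (user tables may use fractional points)
and risk categories compare numerically without rounding: high risk below
15, moderate in [15, 23), low at or above 23 — the half-open convention.

**MDD-W.** One point per MDD-W group with total grams *strictly greater*
than 15 g/day (threshold configurable); grams are aggregated per group
before thresholding. The score is computed for all persons regardless of
sex. The per-item alternative reading of the rule (any single item above
the threshold) can be obtained by scoring items individually, but
aggregate-then-threshold is the package convention.

**UPF share.** NOVA class is an input annotation per item; the share is
100 × (energy of class-4 items) / (total energy). A zero-energy day raises
an error rather than reporting 0, because the share is undefined, not zero.

**First-recall convention.** Metrics are scored from recall day 1 by
default; `day=2` is exposed for sensitivity analyses.

## Usual intakes

Daily intakes x_id for person i, day d are modelled on a transformed scale
(identity, or log(x + 1) for right-skewed micronutrients) as
z_id = μ + b_i + e_id with b_i ~ (0, σ²_B), e_id ~ (0, σ²_W). The
components are estimated by ANOVA method of moments (unbalanced designs use
the standard coefficient n₀ = (N − Σn_i²/N)/(m − 1); a negative
between-person moment is truncated at 0; persons with a single recall
inform only μ). The usual intake is the best linear predictor
μ + λ_k(z̄_i − μ), back-transformed, with λ_k = σ²_B/(σ²_B + σ²_W/k) ∈
[0, 1] non-decreasing in k. This transparent shrinkage estimator stands in
for covariate-based measurement-error models (two-part nonlinear mixed
models): it reproduces the usual-intake *level and ranking* the downstream
analyses require, but not covariate-specific distributions or episodic
(zero-heavy) nutrient handling; the substitution is declared in the output
metadata.

Energy adjustment follows the residual method: regress usual nutrient
intake on usual energy (weighted least squares when person weights are
supplied) and keep residual + fitted value at the reference energy (the
(weighted) sample mean by default, configurable). Ordinary-least-squares
orthogonality makes the adjusted values *exactly* uncorrelated with energy;
the test suite asserts |r| < 1e-10.

## Adequacy

For nutrients with an EAR, PA = F_req(usual) with F_req either
N(EAR, (CV·EAR)²) or a user-tabulated non-decreasing curve
(piecewise-linear interpolation, saturating outside its range) for skewed
requirements such as iron. Nutrients without an EAR (fiber; optionally
protein) can use mode `reference_ratio`: PA = min(1, usual/reference),
flagged as non-probabilistic in the output since it is a capped ratio, not
a probability. Both modes are provided because published practice for
AI-based nutrients varies; the packaged requirement table (illustrative
EAR/CV values) uses the ratio mode for fiber only. MPA is the unweighted
mean of PA over the configured eight nutrients; overall inadequacy is
MPA < 0.5 with a *strict* inequality — MPA exactly 0.5 is adequate.

## Validation statistics

* **Spearman CI**: Fisher z with variance 1.06/(n − 3), the standard
  rank-correlation correction.
* **Dependent-correlation comparison**: the literature leaves the exact
  test ambiguous, so both a default analytic mode — the
  Meng–Rosenthal–Rubin z for overlapping dependent correlations applied to
  Spearman coefficients — and a seeded permutation mode (swap the two
  metrics' values within subject) are provided and named in the output.
  They agree within 0.02 on n = 50 fixtures and both hold the nominal
  type-I error within ±0.02 at α = 0.05 over 1000 null replicates.
* **Quintiles**: cut at the (weighted) 20/40/60/80th percentiles; boundary
  ties all take the lower quintile (cumulative-distribution cutting, so the
  labelling is deterministic). Integer-valued metrics such as MDD-W can
  yield degenerate boundaries; a warning is issued, empty quintile levels
  are omitted from model designs, and their odds ratios reported as NaN.
* **Quintile logistic model**: maximum-likelihood GLM with quintile
  indicators (Q1 reference) plus covariates; ORs are exponentiated
  coefficients with Wald 95% CIs; the trend test refits with the quintile
  as numeric code 0–4. Age enters as three ranges (10–19, 20–59, ≥ 60) in
  the logistic specification and as continuous years in the linear
  specification when the caller passes it so. With no covariates the ORs
  equal the 2×5 contingency-table cross-product ratios exactly (tested).
* **Cross-metric Wald test**: both metrics' quintile dummies in one model;
  (β_A5 − β_B5)²/(V_A + V_B − 2·Cov) against χ²(1). Identical quintile sets
  are rejected up front as rank-deficient. The linear-outcome analogue
  compares first-to-fifth-quintile deltas the same way.
* **Survey design** is simplified to optional person weights (variance
  weights in the fits); stratum/PSU variance estimation is out of scope and
  the simplification is recorded in each result's metadata.
* Separation in a logistic fit raises a convergence error with a
  diagnostic (a coefficient beyond 30 log-odds units is treated as
  divergence) rather than returning unstable estimates.

## Synthetic-data generator

One latent quality factor q_i ~ N(0,1) per person drives everything:

* **food groups**: per person-day, each of the 25 groups is consumed with a
  logit-shifted probability (positive shift for healthy groups, negative
  for unhealthy; base rates chosen so zero-intake prevalence is heavy for
  the groups real recall data rarely capture in a day) and, when consumed,
  contributes a lognormal gram amount whose location also loads on q. Two
  synthetic item ids per group exercise aggregation.
* **outcome coupling**: overall inadequacy is drawn per person from
  logit P = a + b·Q(q), Q(q) ∈ {0..4} the quintile code of q, with
  b the *log-odds per quintile step* (default −0.55, intercept 0.8 →
  roughly 43 % prevalence). Nutrient usual intakes are then placed
  symmetrically above/below their requirement (log-scale separation 0.8 by
  default) consistently with the drawn status, plus between-person jitter
  and within-day lognormal noise with configurable variance components —
  so the usual-intake → adequacy stages can reconstruct the generated
  outcome (>95 % agreement at the defaults) and the fitted quintile trend
  recovers b up to the attenuation induced by measuring quality through a
  scored metric rather than q itself.
* **UPF coupling**: the person-day UPF energy share is logistic-normal with
  the target quality correlation imposed exactly on the logit scale
  (|target| > 0.8 is rejected as infeasible given the share noise);
  class-4 items split the share's energy in proportion to grams.
* **energy**: lognormal with between/within log-variances 0.04/0.0225 —
  known truth used for variance-component recovery checks.
* **covariates**: sex, age range, locality, income, region, supplement
  use, diet modification and a lognormal person weight, drawn independently
  of q with survey-like frequencies.

Identical seeds give byte-identical datasets. What passing tests on this
generator show: the pipeline's algebra, calibration and error handling are
correct under known truth. What they do not show: performance under real
recall phenomena the generator omits — correlated food-group choices beyond
one latent factor, episodic nutrients, recipe disaggregation error, intake
misreporting, or covariate-confounded diet quality.

## Problem sizes and numerics

Default test and acceptance runs use 400–3000-person populations, 1000-way
null-replicate calibrations (n = 150 per replicate for the correlation
test, 800 for the Wald test) and a 10,000-observation trend-recovery fit —
sizes at which the method-of-moments estimators are within 10 % of truth
and type-I errors resolve to ±0.02. Quintile boundary ties, zero-intake
days, constant inputs and single-class outcomes all have defined behaviour
(documented errors or warnings) rather than silent results.
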