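# Methods

## Setting and estimands

Each subject contributes a follow-up time `T` in days and an event code
`D`: 0 = censored (loss to follow-up, a censoring event such as a
subsequent therapy, or administrative end of follow-up), 1 = event of
interest, 2 = competing event (death). Censoring is assumed independent of
the event processes given covariates; competing events are *not* treated
as censoring except inside the deliberately biased "naive KM" comparator.
Arms are a control group plus one or more treatment groups; one arm is the
designated reference.

Two estimands are reported per arm:

* the cumulative incidence `CIF_k(t) = P(T ≤ t, D = k)`, and
* the cause-specific hazard ratio of each treatment arm versus the
  reference, from a proportional-hazards model on the cause-k hazard.

## Nonparametric estimators

Let `t_j` be the distinct times with at least one event of any cause,
`n_j` the (weight-summed) number at risk (`T_i ≥ t_j`; subjects censored
at `t_j` are still at risk there) and `d_kj` the (weight-summed) cause-k
events at `t_j`. Ties within and across causes are pooled at a single
`t_j`.

* All-cause Kaplan-Meier: `Ŝ(t) = Π_{t_j ≤ t} (1 − Σ_k d_kj / n_j)`.
* Naive KM CIF of cause k: `1 − Π (1 − d_kj/n_j)`, i.e. competing causes
  censored. Provided only as the biased comparator; it equals the
  Aalen-Johansen estimate when no competing events occur and is otherwise
  an over-estimate (dominance is asserted in the report stage and the
  tests).
* Aalen-Johansen CIF: `Σ_{t_j ≤ t} (d_kj/n_j) · Ŝ(t_j−)` with `Ŝ` the
  all-cause KM left limit. This discretization satisfies
  `Σ_k CIF_k + Ŝ = 1` at every event time to rounding error, for any
  weights.

With IPT weights, all counts become weight sums; estimators on a weight
vector of ones equal the unweighted estimators exactly, and integer
weights are equivalent to row replication (both are test invariants).

Pointwise variance: Greenwood's formula is attached to unweighted KM
curves. For any weighted statistic no closed-form variance is attached;
interval estimation goes through the subject-level bootstrap (percentile
intervals, weights re-estimated inside every resample, degenerate
replicates counted and excluded). The bootstrap treats the subject, not
the event, as the exchangeable unit.

## Stabilized IPT weights

Stage 1 is a binary logistic model for case (any treatment) versus
control on the full cohort; stage 2 a single multinomial-logistic model
for the treatment received, fitted on cases only (never one-vs-rest).
Controls receive `P(control)/P(control|X)`; cases receive
`[P(case)/P(case|X)] · [P(arm)/P(arm|X, case)]`. Numerators are marginal
observed proportions (intercept-only models) — the standard stabilization,
giving mean weight ≈ 1; stage-2 numerators are arm proportions among
cases. With exactly two arms a single-stage binary weight is used.

Truncation limits extreme weights at a percentile (default 99) of the
*raw* weight distribution, computed with linear interpolation between
order statistics (conventions differ across software, so this is stated
explicitly). Default mode caps at the percentile value, which preserves
the sample and is idempotent because the threshold is a functional of the
raw weights; a delete mode removes the subjects above the threshold and
records them. Denominator probabilities below a configurable floor
(default 1e-6) flag the subject in the result rather than failing.

Balance is summarized by standardized mean differences per covariate
(categoricals expanded to indicators) for each arm versus the reference,
before and after weighting, with weighted variances using a frequency-
weight ddof-1 correction so unit weights reproduce the unweighted SMD
exactly; the per-arm weight mean, maximum and effective sample size
`(Σw)²/Σw²` are reported alongside.

## Weighted cause-specific Cox model

Events of other causes are censored at their event time (cause-specific
formulation; no subdistribution modelling). The weighted partial
likelihood is maximized by Newton-Raphson from β = 0 with step halving,
stopping when the largest coordinate update is below 1e-9 or the relative
log-likelihood change is below 1e-12; 100 iterations or any |β| > 20
raises an error (the latter indicates a monotone likelihood / separation,
for which no finite MLE exists). Ties: Breslow by default — the common
default in weighted proportional-hazards practice — with Efron available.

Reported covariance is always the robust sandwich `I⁻¹ (Σᵢ UᵢUᵢᵀ) I⁻¹`
with `Uᵢ` the weight-multiplied score residual of subject i; the naive
model-based variance is invalid under weighting and is retained only as a
diagnostic. Score residuals use the Breslow form also under Efron ties
(the difference vanishes without ties and is negligible at the tie rates
the package targets). The sandwich is invariant to rescaling all weights
by a constant. CIs are `exp(β ± z_{0.975}·SE_robust)`. The implementation
is cross-checked in the test suite against lifelines (coefficients and
robust standard errors to ~1e-8) and against a brute-force partial-
likelihood maximization on small fixtures.

Adjustment covariates enter linearly; age is continuous, comorbidity and
baseline-event history are categorical indicators. Weight truncation is
applied before fitting.

## Synthetic cohort generator

The generator emulates the structure of an elderly matched-cohort
treatment study: age = 66 + Exponential(mean 8) years (capped at 100),
race ∈ {white, black, other} with probabilities (0.83, 0.10, 0.07),
comorbidity ∈ {0, 1, 2} (0.55, 0.25, 0.20), baseline event history
Bernoulli(0.15), and a standard-normal socioeconomic index. Arms (control
plus EBRT, BT, BT+EBRT, RP, RP+EBRT, cryotherapy) are drawn from a
multinomial-logistic model on these confounders; intercepts put roughly
29% of subjects in control and 10–14% in each treatment arm — deliberately
more balanced than a real registry, so that per-arm hazard ratios are
estimable with small Monte-Carlo error at the default n = 20,000.

Cause-specific hazards are constant given covariates (exponential times,
proportional-hazards form): baseline 1.1e-4/day for the event of interest
and 0.9e-4/day for death, independent exponential censoring at 4e-5/day,
administrative censoring at 3650 days. True cause-1 arm hazard ratios
default to {1.2, 1.6, 2.2, 2.8, 3.7, 1.75} (EBRT … cryotherapy) and
cause-2 ratios are all below 1, so the control arm has the highest death
incidence — the qualitative pattern such cohorts show when healthier men
are selected into screening and treatment. SES and race affect both
assignment (most strongly for RP+EBRT and cryotherapy) and both hazards,
but are *excluded* from the default outcome-model adjustment set
(age, comorbidity, baseline event): they are handled only through the
weights. This is what creates the built-in confounding bias of the
unweighted fit (>15% on the two designated arms) that weighting must
remove.

Design rationale, fixed once: confounder effects on the hazards are kept
modest (≤ 0.3 on the log scale for the unadjusted confounders) so that
hazard-ratio non-collapsibility — the weighted, partially adjusted fit
estimates a slightly attenuated marginal contrast — costs only ~2–4%,
small against the 10% recovery budget; assignment coefficients up to 1.0
on the SES index make the designated arms' unweighted bias ~20–40% while
keeping the stabilized weights tame (max ≈ 2.6 after the 99th-percentile
cap). Event rates are higher than in the motivating application (control
10-yr CIF ≈ 35% rather than ~12%) so that per-arm event counts at
n = 20,000 keep the Monte-Carlo error of each log-HR near 0.04.

The constant-hazard truth is
`CIF_k(t) = λ_k/(λ₁+λ₂)·(1 − e^{−(λ₁+λ₂)t})` (checked against numerical
quadrature of `∫ λ_k S`); a Weibull-shape extension is deliberately out of
the validated surface. No exact cross-cause ties are generated (times are
continuous); tie handling is exercised by hand-built fixtures, including
the canonical 10-subject worked example whose companion text walks through
the full risk-set arithmetic in rational numbers.

What passing tests on this generator do *not* show: robustness to
propensity-model misspecification (the analysis model matches the
generating model), informative censoring, time-varying hazards or
treatment, claims-coding noise, or matched-sampling artifacts of real
registry cohorts.

## Numerical choices and scales

* Times are days; the default reporting horizon is 3650 days ("10-year"),
  configurable.
* Events at a time t are counted before censorings at t (both remain in
  the risk set at t).
* Step functions are right-continuous; evaluation beyond the last jump
  returns the last value.
* Percentages are rounded only at render time (one decimal for CIFs, two
  for HRs); all internal arithmetic is full precision.
* Problem sizes used by the test suite and acceptance script — 50,000
  subjects for closed-form consistency, 20,000 for confounding-bias
  removal, 1,000 fuzzed mini-cohorts for the brute-force oracle, 300
  cohorts × 200 bootstrap replicates for coverage — were chosen as the
  smallest sizes at which the expected statistical margins comfortably
  exceed Monte-Carlo noise.

## Known limitations

* Cause-specific hazards only; no Fine-Gray subdistribution regression.
* No time-varying weights/covariates, left truncation, or stratified
  baselines.
* The percentile-bootstrap CIF interval slightly under-covers (≈ 93–95%
  observed) at moderate event counts, as percentile intervals typically
  do; coverage is verified in the acceptance suite rather than assumed.
* Perfect separation in propensity or Cox models is detected and raised,
  not penalized away; users with sparse arms must coarsen or penalize
  upstream.
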