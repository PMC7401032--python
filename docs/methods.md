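# Methods

This note records the statistical models implemented in `deftmeta`, the
defaults and numerical choices, what the synthetic-data generator does
and does not emulate, and the known limitations.

## The estimand

Throughout, the target is the within-trial treatment–covariate
interaction γ_W: the change in the treatment effect (mean difference,
log odds ratio, log risk ratio, or log hazard ratio) per one-unit
increase in a participant-level covariate, estimated only from
covariate variation *inside* trials. Associations between trial-level
covariate means and trial-level treatment effects (the across-trial
coefficient γ_A) are kept strictly separate: they are observational,
confounded by anything else that differs between trials, and mixing
them into γ_W produces aggregation (ecological) bias.

## Two-stage analysis

Stage one fits, in each trial separately, a regression of the outcome
on intercept, covariate, treatment, adjusters, and the
treatment-by-covariate product. The baseline outcome value is adjusted
for whenever a `baseline` column is present; further adjusters are a
user-supplied list applied identically in every trial and dropped per
trial when constant (logged). Continuous outcomes use least squares
with a single residual variance for both arms and the unbiased
(residual-df) σ̂_i²; binary outcomes use a binomial GLM with logit
(log-OR interaction) or log link (log-RR); time-to-event outcomes use
Cox partial likelihood with the Efron tie correction — the standard
choice, and the baseline outcome value is treated as an ordinary
adjuster there. All first-stage variances are Wald variances, matching
the normal-within-trial assumption of the second stage. Trials with a
single arm, zero covariate variation, separation, zero events per arm,
or monotone likelihood are flagged inestimable and excluded from
pooling, never silently imputed.

Stage two pools by inverse variance. τ² is estimated by REML — computed
by direct bounded maximization of the restricted log-likelihood
(Brent, absolute tolerance 1e-12 on τ², floored at zero), which is
equivalent to, and more robust than, iterating the REML estimating
equation — or by DerSimonian–Laird. Confidence intervals default to
HKSJ: the pooled variance is rescaled by the weighted residual sum of
squares over k−1 and a t-quantile with k−1 degrees of freedom is used;
the scale factor is *not* truncated at 1 by default (plain HKSJ, with a
switch). Prediction intervals use γ̂_W ± t_{k−2}·√(τ̂² + se²) (the
Higgins convention for the degrees of freedom) and require k ≥ 3.

## One-stage analysis

Two deft specifications are fitted on all rows at once:

* **Centered + meta-regression**: stratified intercepts and stratified
  prognostic effects; treatment effect with fixed mean φ + γ_A·z̄_i and
  a trial-level random deviation (variance τ₁²); interaction slope on
  x·(z − z̄_i) with fixed mean γ_W and random deviation (variance τ₂²).
  Centering plus the z̄_i meta-regression makes γ̂_W and γ̂_A
  (essentially) orthogonal, so γ̂_W carries only within-trial
  information.
* **Fully stratified**: every nuisance parameter — intercept, covariate
  and adjuster effects, and the per-trial treatment effect β_2i — is a
  fixed effect per trial; the interaction slope is the only random
  effect (variance τ²). Under REML, placing the random slope on the
  trial-mean-centered product x·(z − z̄_i) is exactly equivalent to the
  uncentered product (the REML error contrasts annihilate the per-trial
  treatment columns) and is much better conditioned, so the centered
  column is used internally.

The **amalgamated ("deluded") model** — uncentered x·z interaction,
random treatment effect, no z̄_i term — is implemented for diagnosis
only (continuous outcomes); every output carries a warning label, and a
side-by-side deft-vs-deluded table is available.

**Continuous outcomes** are fitted by REML with *trial-specific*
residual variances σ_i², using a solver written for the per-trial
block covariance σ_i² I + Σ_c τ_c² g_ic g_ic′ (rank ≤ 2 per trial):
each likelihood evaluation uses precomputed per-trial sufficient
statistics (M′M, U′M, U′U) and Woodbury identities, so evaluations cost
microseconds and the optimization (L-BFGS-B on square-root-scale
parameters, ftol 1e-13, Nelder–Mead fallback) is fast and reliable.
Variance components are floored at zero; fixed-effect columns are
centered per trial for conditioning; identically-zero columns (e.g. the
stratified covariate effect of a constant-covariate trial) are dropped.
A `residual_variances="common"` switch fits a single shared σ² — this
is the model statsmodels' MixedLM fits, which serves as an independent
cross-check in the test suite. Trial-specific σ_i² is the default
because the per-trial models of the two-stage analysis have their own
residual variances, and matching that assumption is what makes one- and
two-stage REML results practically identical on balanced data (the test
suite asserts agreement within 0.01·SE at 10 trials × 500
participants).

**Satterthwaite intervals** for the interaction use
df = 2·f²/(gᵀH⁻¹g), with f(θ) = var(γ̂_W | θ), g its central-difference
gradient over the variance components, and H the observed information
of the restricted likelihood (numerical Hessian); variance components
on the zero boundary are held fixed. This yields t-intervals slightly
wider than Wald for small numbers of trials, closely matching the
two-stage HKSJ width.

**Binary outcomes** use a Bernoulli-logit mixed model estimated by
maximum likelihood with per-trial adaptive Gauss–Hermite quadrature
(default 9 nodes per dimension; one random effect for the stratified
approach, a 2-D tensor grid for the centered approach). The quadrature
is centered and scaled at the per-trial posterior mode of the random
effects (Newton iterations), so moderate node counts are accurate;
sensitivity to the node count is negligible above ~7 nodes in the
settings exercised by the tests. Standard errors come from the
numerical observed information over all parameters. One-stage Cox
models are deliberately out of scope; survival outcomes go through the
two-stage route.

## Restricted cubic splines and multivariate pooling

The RCS basis with K knots (K ∈ {3,4,5}, default 3) has K−1 columns:
the covariate itself and truncated-cubic terms normalized by the
squared outer-knot span (k_K − k_1)². This normalization is what makes
the published age-basis values come out as printed (second basis value
0.00077 at age 40 and centering constant 3.16 at age 55 for knots
39/60/75). Default knot placement follows Harrell's quantile
recommendation (10/50/90% for K = 3) computed on the *pooled* covariate
distribution: knots must be identical in every trial for the per-trial
coefficients to be poolable, so per-trial placement is not offered.

Per-trial spline fits regress the outcome on the basis main effects,
treatment, adjusters, and treatment × (basis centered at the shared
reference value), so the treatment coefficient is the effect for a
reference individual and the interaction slopes are comparable across
trials. Interaction components whose centered basis column shows no
variation among that trial's treated participants (covariate window not
reaching the relevant knots) are masked, not extrapolated.

The per-trial vectors (β̂_2i, γ̂_W1i, γ̂_W2i, …) are pooled by
multivariate REML: the restricted log-likelihood over the observed
subvectors (masked components enter through the marginal likelihood —
numerically stable and exactly equivalent to the
infinite-variance-augmentation trick in the limit), with the
between-study covariance parameterized as unstructured (Cholesky),
diagonal (recommended when k is small), or zero, and maximized by
Nelder–Mead from component-wise univariate REML starts. Pooling the
interaction slopes *without* the reference component
(`include_reference=False`) prevents them from borrowing across-trial
information through their correlation with β̂_2i; these de-biased
coefficients feed the corrected prediction equation. A component
observed in fewer than two trials is declared inestimable with an
error; a non-PSD within-trial covariance is fatal for that trial with a
repair hint.

Summary curves report Σ_m γ̂_m (basis_m(x) − basis_m(ref)) on a default
grid of 100 points with delta-rule pointwise intervals; the value and
interval width are exactly zero at the reference. Prediction equations
add β̂₂ and treat the pooled coefficients as fixed (no τ² inflation by
default — intervals reflect the sampling covariance of the pooled
means, which is how the source curves are presented; a prediction-style
widening can be layered on by the user from the reported ψ̂).
Extrapolation beyond the observed covariate range is flagged, not
blocked.

## Subgroup diagnostic

For a binary covariate, `subgroup_contrast` runs a full random-effects
meta-analysis of the *overall* treatment effect within each covariate
level, prints the difference of the two summaries next to the deft
within-trial pooled interaction, and labels the former "subgroup
difference is NOT a valid interaction estimate". The per-trial weight
table makes the mechanism visible: a trial containing only one subgroup
has positive weight in that subgroup's summary and exactly zero weight
in the interaction. Forest tables for interaction estimates carry
circle-marker metadata to distinguish them from treatment-effect forest
plots.

## Power

The closed-form calculator assumes continuous outcomes, a common
interaction (no between-study heterogeneity — heterogeneity scenarios
are simulation-only), and per-trial interaction variances
4σ_i²/(n_i σ_zi²) for equal-sized arms (the general form
4σ_i²/(Σ z′²) with per-arm sums of squares about the trial mean reduces
to it exactly under balance). Missing σ_i² or σ_zi² entries in a
planning table are imputed by the n-weighted average of the available
trials; the total outcome variance is accepted as a proxy when the
residual variance is unpublished. Power at two-sided threshold z is
Φ(−z + |γ_W|/√v) + Φ(−z − |γ_W|/√v), which equals the type-I error at
γ_W = 0.

The simulation calculator draws, per replicate, Gaussian covariates and
outcomes matching the planning table (1:1 arms unless arm sizes are
given, per-trial interactions N(γ_W, τ²)), runs the two-stage analysis
(a numpy least-squares first stage — asserted in the tests to match the
public per-trial fit to 1e-8 — followed by common-effect or
random-effects pooling), and reports the rejection proportion with its
Monte-Carlo SE. Significance is judged by the same CI method the user
plans to use (Wald default, HKSJ option). Replicate-level failures are
excluded and warned about above 5%.

## Synthetic data

The generator emulates S parallel-group trials with trial-specific
covariate means/SDs (optionally truncated windows, or a binary
covariate with prevalences spread 0.23–0.70 across trials),
trial-specific intercepts, a prognostic covariate effect, an optional
baseline outcome acting through β₃ (which is what makes baseline
adjustment consequential), trial-specific interactions
γ_Wi ~ N(γ_W, τ²), and a treatment effect
φ + γ_A(z̄_i − mean z̄) + γ_Wi(z − z̄_i) — the across-trial term is
parameterized on centered trial means so φ keeps its interpretation at
the average trial. Outcomes are Gaussian, Bernoulli-logit, or
exponential survival with uniform administrative censoring. Defaults
describe an antihypertensive-like setting: 10 trials × 200 participants
(1:1), residual SD 10 mmHg, φ = −10 mmHg, age-like covariate with trial
means spread 45–75 (SD 10), γ_W = −0.1 per year, τ² = 0, γ_A = γ_W.
Fixed seed ⇒ bit-identical output.

What it does *not* emulate — and what passing tests therefore do not
demonstrate about real data: missing-data mechanisms (analyses are
complete-case per model, with counts logged), covariate measurement
error, informative censoring, non-proportional hazards, cluster/
crossover/multi-arm designs, and non-Gaussian covariate laws beyond the
options above.

## Problem sizes used in the checks

The heavier verification runs were sized as follows: cross-method
agreement at 10 trials × 500 participants; aggregation-bias separation
over 300 replicates of 6 trials × 120 (mean-bias bands scale with the
Monte-Carlo SE, so the check is calibrated at any replicate count);
power-engine agreement over a 6-scenario grid at 500 replicates each
plus a 1000-replicate null; the trial-variance Monte-Carlo at 2000
simulated trials; REML heterogeneity calibration and HKSJ coverage at
1000 replicates of 10 studies.

## Known limitations

* One-stage survival (frailty) models are not provided; use two-stage.
* The deluded model is intentionally restricted to continuous outcomes.
* Multivariate REML with an unstructured ψ and few trials can sit on
  boundary solutions; the diagonal structure is the recommended fallback
  and the convergence log is attached to every result.
* The centered one-stage approach is invariant to shifting one trial's
  covariate only up to the (1, z̄_i) meta-regression reweighting
  (order 0.01·SE); exact invariance holds for the fully stratified
  approach.
* Categorical covariates are handled by reference-level indicator
  coding with one interaction per indicator; ordinal structure is not
  exploited.
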