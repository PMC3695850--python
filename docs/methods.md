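# Methods

## Data model

A study is a repeated-measures panel: n patients, K measurement points
at months t(1)=0 < … < t(K) (default 0, 3, 7, 9, 12), an effectiveness
score E_ik ≥ 0 per point (a symptom severity index, larger = worse), and
an interval cost C_ik ≥ 0 (euros) for each of the K−1 gaps. Patients are
dichotomized into low/high groups at a threshold on a continuous
baseline score (default 4.0, with ≥ mapping to high), and carry baseline
confounders: gender, a diagnostic category, three continuous scales, and
the baseline score of the effectiveness instrument. Missing values (NaN)
are allowed everywhere and are never dropped silently.

Per patient the panel is summarized by the cumulative cost
C_i = Σ_k C_ik and the effectiveness AUC — the trapezoid area of the
score over follow-up divided by t(K), so it lives on the score scale.
The incremental cost-effectiveness ratio ICER = Δcost/Δeff uses
differences oriented low − high throughout; |Δeff| ≤ 1e−6 (configurable)
marks the ICER undefined, which is reported as a flag, not an error.
Because larger scores mean worse symptoms, the usual interpretation of
the cost-effectiveness plane's quadrants is mirrored about the vertical
axis; the CE-plane export notes this.

## Estimation strategies

### Unadjusted bootstrap

Patients are resampled with replacement stratified by group (group sizes
preserved exactly; patients with missing group are excluded from the
frequentist paths). Inside every replicate one fresh single imputation
completes the outcomes, then group means, differences, and the ICER are
computed. Summaries over B replicates (default 500): mean, SD as the
standard error, percentile 2.5/97.5 interval, and the two-sided
sign-inversion p-value p = 2·min(#{Δ* ≤ 0}, #{Δ* ≥ 0})/B. Replicates
with an undefined ICER are excluded from the ICER summaries and counted;
more than 50% undefined marks the ICER summaries unusable.

### Imputation

Missing scores and interval costs are imputed jointly under a
multivariate normal model over the 2K−1 outcome columns, fitted
separately within each group (no auxiliary covariates). The
data-augmentation chain alternates an I-step (each patient's missing
block drawn from its conditional normal given the observed block and the
current (μ, Σ)) and a P-step (Jeffreys-prior posterior draw:
Σ ~ InvWishart(n−1, S), μ | Σ ~ N(ȳ, Σ/n)). Nonmonotone missingness
patterns are grouped once and the I-step is performed as a joint draw
W ~ N(μ, Σ) plus the exact conditional-mean correction
−Λ_mm⁻¹(Λd)_m (Λ = Σ⁻¹, d the observed residual zero-filled at missing
cells), which makes an iteration a handful of batched matrix
operations.

Interval costs enter the normal model on the raw euro scale and imputed
values are clamped at zero. The conditional mean of a normal is linear,
so raw-scale imputation is approximately unbiased for means even though
the cost distribution is semicontinuous; an optional log1p/expm1 variant
exists but is not the default, because the zero spike gives the log-scale
columns conditional variances around 8 at the late intervals and the
expm1 back-transformation then inflates imputed cells by
exp(σ²/2) — more than an order of magnitude. Imputed scores are clamped
at zero (the instrument's floor). Observed cells are never altered.

Defaults: burn-in 200 and thinning 100 between imputations for the
m-imputation path; the per-bootstrap-replicate single imputation uses a
shorter burn-in of 40, justified by initializing the chain at the
group-wise observed-moment estimates (a consistent starting point, so
the chain starts essentially in its stationary region; this is a
Monte-Carlo-efficiency choice that keeps resampling studies cheap).

### Frequentist predictive margins

On a completed dataset, the cumulative cost is fitted by a gamma GLM
with log link (the design's cumulative costs are all positive; a
non-positive response raises an error pointing to two-part handling) and
the AUC by OLS, both on intercept + confounders (+ baseline score for
the effectiveness model) + group. The predictive margin of a level is
the average model prediction over all n patients with everyone's group
indicator forced to that level — standardization over the estimation
sample, so with an identity link the margin difference equals the group
coefficient exactly and with a log link the margin ratio equals
exp(coefficient). The adjusted ICER is the ratio of margin differences.
Uncertainty comes from the same stratified bootstrap-with-imputation
driver; replicates whose fit fails (e.g. a resample losing a covariate
level) are skipped and counted rather than refitted with a reduced
model.

### Bayesian hierarchical two-part model

Per patient i, interval/point k (post-baseline):

- Z_ik ~ Bernoulli(logit⁻¹(X_ik β_z)) — any cost incurred;
- P_ik ~ Gamma(shape = exp(X_ik β_p + U_i3)·τ_gk, rate = τ_gk), so the
  conditional mean is exp(X β_p + U_i3) and the conditional variance is
  mean/τ; τ_gk free per group × interval captures the strong
  heteroscedasticity of positive costs (large early, small late);
- E_ik ~ N(X_ik β_e + U_i1 + U_i2·t_k, σ²_gk) with per-group-and-point
  residual variances; the baseline score is a covariate, not an outcome.

U_i = (U_i1, U_i2, U_i3) ~ N(0, Σ_U); the correlations ρ_jl of Σ_U
quantify the cost–effectiveness association unexplained by covariates.
There is deliberately no random effect on the zero-cost part (near-zero
prevalence of zeros in the early intervals would leave it unidentified).

Priors: coefficients N(0, 100) — read as variance 100 by default, with a
precision-convention switch; σ² ~ InverseGamma(3, 1);
τ ~ Gamma(3, 1); Σ_U ~ InverseWishart₁₀(I₃). Missing-data models:
group indicator ~ Bernoulli(p), p ~ Uniform(0, 1); each continuous
baseline covariate column that contains missing values gets
x_ij ~ N(μ_j, 1/τ_j) with μ_j ~ N(0, 1000), τ_j ~ Gamma(2, 1) (the whole
column enters the covariate model, so observed values inform the
hyperparameters). Missing categorical covariates are not augmented; the
generator never deletes them.

Note the Gamma(3, 1) prior on τ is informative where the truth is large
(prior mean 3 against dispersions near 12 in the first interval), so
posterior dispersion summaries are shrunk toward smaller values while
their ordering across intervals is preserved; the same applies to the
InverseWishart prior when a random-effect variance is tiny (the slope
component). These are properties of the stated priors, not of the
sampler.

#### Sampler

Metropolis-within-Gibbs, fully vectorized over patients and cells:

- conjugate draws for β_e (heteroscedastic weighted least squares with
  ridge 1/prior-variance), σ²_gk (inverse gamma), Σ_U (inverse Wishart
  via a Bartlett draw), (U_i1, U_i2) per patient (2×2 closed-form
  Cholesky), and the covariate-model and group-probability
  hyperparameters;
- adaptive random-walk Metropolis for the β_z and β_p blocks, log-scale
  per-component Metropolis for τ_gk, and per-patient random-walk updates
  for U_i3, all with Robbins–Monro scale adaptation during burn-in;
- block proposal shapes are refreshed mid-burn-in: β_z from the
  empirical covariance of its own history, β_p from the conditional
  Fisher information (X' diag(mτ) X)⁻¹ — the conditional posterior of
  β_p given U₃ is orders of magnitude tighter than its marginal GLM
  covariance because gamma shapes mτ run in the thousands;
- reparameterization ("shift") moves trade each measurement-constant
  column of the positive-cost design (intercept, confounders, group)
  against U₃: β_j → β_j + δ, U_i3 → U_i3 − δ·x_ij leaves the likelihood
  invariant, so acceptance involves only the priors. These directions
  are identified solely by the random-effects prior; without explicit
  moves along them the chains diffuse pathologically slowly (observed
  split-chain scale reductions above 100 before the fix);
- exact conditional draws for every augmented quantity: missing scores,
  missing cost cells (indicator then magnitude), missing group
  indicators (two-sided likelihood evaluation), and scalar
  random-walk Metropolis for missing continuous covariates.

Initialization: coefficients at complete-case GLM estimates (zeros on
failure), variances at 1, Σ_U at identity, missing values at simple
moment-based fills. Default chains: 2 × 4000 kept after 1000 burn-in,
thin 1 — a reduced configuration chosen so seeded recovery studies
complete quickly; `MCMCSettings.paper_scale()` (and `--paper-scale` on
the CLI) switches to 2 × 60,000 kept after 10,000 burn-in with thinning
15. A non-finite log density at initialization raises immediately;
convergence heuristics only warn.

#### Posterior predictive margins

For each retained draw the observed patients form a hypothetical cohort
twice — group forced to low, then to high — with fresh random effects
per cohort member and augmented covariate cells filled from the same
draw; outcomes are simulated from the model, cohort means of cumulative
cost and AUC (baseline score as the AUC's first support point) are
differenced, and the ICER is formed per draw. Posterior means, SDs and
central credible intervals summarize; draws with an undefined ICER
denominator are excluded from the ICER quantiles and their fraction
reported.

## Diagnostics

A random holdout (default 40 patients) is excluded from fitting; its
outcomes are predicted from baseline information alone. The
standardized predictive error (SPE) of an observed score is the
posterior average of (predicted mean with fresh random effects −
observed)/residual SD. For positive costs, the observation is
standardized against the draw's full predictive mean and SD with the
cost random effect integrated out (lognormal-gamma moments);
standardizing by the gamma's conditional SD alone would be degenerate —
that SD is a percent-level fraction of the random-effect variation, so
every value would be tens of units wide even under the true model.
Q-Q coordinates against N(0, 1) and per-measurement-point
Kolmogorov–Smirnov statistics summarize the fit.

Note the effectiveness SPE divides by the residual SD only, so across
subjects its spread is √((σ² + var_U)/σ²) even under the true model;
the calibration experiments therefore use a scenario whose
random-effect variances are small relative to the residual variance.
With the default scenario's random-intercept SD the same check would
reject for a reason implied by the statistic's own definition, not by
any model defect.

Convergence summaries: split-chain potential scale reduction and lag-1/
lag-10 autocorrelations per scalar parameter, flagging values above 1.05
(with a single chain the scale reduction is omitted with a warning).

## Synthetic-data generator

The generator draws baseline confounders from configurable marginals,
assigns the group by a logistic model in the standardized confounders
(inducing confounding by construction), synthesizes a continuous group
score consistent with the assignment, and then simulates outcomes from
the hierarchical two-part model itself. Missingness is superimposed
afterwards — MCAR, or MAR driven by always-observed baseline covariates
so that ignorability holds by construction — and the complete data ride
along as ground truth.

The default scenario (n = 200, months 0/3/7/9/12) is calibrated to a
one-year psychotherapy panel: near-zero zero-cost prevalence in the
first two intervals and ~35–40% in the last two; positive-cost
dispersions descending from 12 to 2 (low group) and 8 to 2 (high group)
across intervals; residual score variances around 0.07–0.17; cumulative
mean costs near 1,900 €; declining scores with a baseline-score
coefficient of 0.65; a small true group effect (0.05 score units,
~8% costs); random effects with var(U₁) = 0.15, var(U₂) = 4·10⁻⁴,
var(U₃) = 0.15 and a generating ρ₁₃ of 0.5; and MAR missingness rising
from ~9% to ~18% (scores) and ~12–15% (costs) with 2.5% missing group
scores and ~1% missing continuous covariates. Effectiveness is generated
unbounded (the model is normal); a clamp-at-zero option exists for
realism experiments but defaults off so model-validation tests see the
model's own distribution.

Stock variants: `null_effect_scenario` (zero group coefficient in all
three models — the adjusted estimand is exactly zero while the raw
contrast stays confounded), `spe_scenario` (small random-effect
variances, for predictive-error calibration) and
`spe_misspecified_scenario` (standardized lognormal score noise at the
last two points, for misfit detection).

What the generator does not emulate: item-level instrument scoring,
correlations among baseline confounders beyond those induced by group
assignment, actual (per-patient) measurement times, and any
non-ignorable missingness. Passing recovery and coverage tests on these
scenarios demonstrates internal validity of the estimators under the
model's own assumptions, not robustness to real-data departures from
them.

## Numerical choices and scale

Tolerances: ICER undefined below |Δeff| = 1e−6; design ridge 1e−8 in the
WLS initializer; imputation covariance ridge 1e−6. Problem sizes in the
test suite are chosen for single-CPU runs: recovery uses 20 seeds at
n = 200 with 2 × 4000 kept draws; coverage suites use 100–200
replications with B = 100 bootstrap; predictive-error calibration uses
n = 400 with a 60-patient holdout and ~2 × 500 kept draws, while the
misfit-detection experiment holds out 200 patients — the KS statistic
gains power against skew-only departures slowly with sample size, and a
stronger injected skew paradoxically *weakens* it (the standardized
lognormal degenerates toward a constant plus rare outliers). The
acceptance script runs the full default pipeline (B = 500, 2 × 4000
draws) in a few minutes.

## Known limitations

- The shared-coefficient formulation ties regression coefficients across
  measurement points (points enter as dummies); fully point-specific
  coefficient vectors are not implemented.
- The frequentist path drops patients with a missing group or missing
  confounders (complete-covariate analysis); only the Bayesian path
  augments them.
- Posterior dispersion estimates inherit visible shrinkage from the
  informative Gamma(3, 1) prior when true dispersions are large.
- The predictive margins use the estimation sample as the standard
  population; no external standardization population is supported.
- Gamma GLM dispersion is estimated by the Pearson method and affects
  only standard errors, never the margins themselves.
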