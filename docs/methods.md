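# Methods

## The selection model

The package targets the classical two-equation sample-selection model
(Tobit type 2). Outcome and selection are linear in their covariates with
jointly normal errors:

    y*_i = x_i'β + μ_i,        s*_i = z_i'γ + ν_i,
    (μ_i, ν_i) ~ N2(0; σ², 1; ρσ),     s_i = 1{s*_i > 0},

and y_i = y*_i is recorded only when s_i = 1. The outcome covariates x are a
subset of the selection covariates z; a z-covariate excluded from x (the
exclusion restriction) is strongly recommended and its absence triggers a
logged warning, since identification then rests on the nonlinearity of the
inverse Mills ratio alone.

**Two-step.** Probit of s on Z over all rows; OLS of y on [X, λ(Zγ̂)] over
selected rows. σ̂² is the step-2 residual variance plus the truncation
correction mean(δ_i)·λ̂², δ_i = λ_i(λ_i + c_i); ρ̂ = λ̂-coefficient / σ̂,
clamped to ±0.99 with a warning. The reported step-2 standard errors are the
*unadjusted* OLS ones: they ignore the estimation error in γ̂ and the
heteroskedasticity induced by truncation, so they are a diagnostic, not the
primary inference. FIML standard errors are the inferential output.

**FIML.** Unselected rows contribute log Φ(−z'γ); selected rows contribute
the normal log-density of y plus log Φ[(z'γ + (ρ/σ)(y − x'β)) / √(1−ρ²)].
ρ is parameterized as tanh(t) and σ as exp(ls) so the problem is
unconstrained; the outcome is standardized internally so every coordinate is
O(1). Optimization is BFGS with the analytic gradient, followed by up to five
damped Newton steps on the numerically differentiated observed information
(BFGS line searches can stall in the nearly flat ρ direction; the polish
drives the max gradient below 1e-6, and the fit is flagged non-converged
above 1e-4). Standard errors invert the observed information in the
transformed space and are delta-method mapped back; the standard error of
lambda = ρσ uses the (t, ls) block. Starting values come from the two-step
fit, falling back to OLS-on-selected + probit + ρ = 0.

**Binary outcomes.** The bivariate probit with selection replaces the
normal outcome density with Φ2 terms: P(y=1, s=1) = Φ2(x'β, z'γ; ρ),
P(y=0, s=1) = Φ(z'γ) − Φ2. Φ2 is computed from Owen's T function
(scipy.special.owens_t), which is analytically exact and fast enough to sit
inside the optimizer; it is validated in the tests against scipy's Genz
integrator at 1e-8. Average marginal effects of a binary covariate on
P(y=1) = Φ(x'β) are averaged over *all* rows, selected or not, because the
estimand is the population outcome probability, not the observed-sample one.

**Test of endogenous selection.** `test_rho_zero` is a likelihood-ratio test
of ρ = 0 against χ²(1). Under the null the likelihood factorizes, so the
restricted maximum is closed form (full-sample probit plus Gaussian ML on
the selected rows) — no second optimization. The Wald statistic on atanh ρ̂
is reported alongside; a two-step fit downgrades to Wald-only with a logged
note.

## The synthetic cohort generator

The generator emulates a pregnancy-surveillance cohort with missing birth
weight. Per subject:

| field     | distribution / rule                               | default |
|-----------|---------------------------------------------------|---------|
| treat     | Bernoulli(p_treat), independent of everything     | p = 0.5 |
| distance  | Uniform(0, dist_max) km                           | 0–10 km |
| knowledge | standard normal (latent)                          | —       |
| bw_true   | bw_mean + beta_treat·treat + knowledge_effect·knowledge + e | 3000 + 50·t + 100·k + e |
| e         | N(0, bw_sd² − knowledge_effect²)                  | sd ≈ 489.9 g |

The stated mean 3000 g / SD 500 g is interpreted as the distribution of
untreated births including the knowledge component, so the idiosyncratic SD
is √(500² − 100²): both printed moments hold simultaneously. p_treat = 0.5
is the neutral, precision-maximizing default for an unspecified exposure
rate; the bounded uniform distance keeps selection probabilities away from
0/1 and gives the exclusion restriction real variation.

Missingness regimes:

* **MAR** — i.i.d. Bernoulli masking of the outcome at rate 0.40 (an
  independent coin per subject rather than an exact 40% subsample;
  statistically equivalent at n = 10,000).
* **MNAR** — selected iff α0 + α_t·treat + α_k·knowledge − α_d·distance +
  ε > 0 with ε ~ N(0,1) independent of e. Defaults α_t = 1.0, α_k = 1.0,
  α_d = 0.25/km; α0 is calibrated by quadrature + root finding so the
  population observed rate is 0.60, matching the MAR scenario. All
  cross-equation correlation flows through knowledge, so the composite
  errors are exactly bivariate normal with ρ = α_k·100 / (500·√(1+α_k²)) ≈
  0.141 — the selection model is correctly specified by construction.

The positive treatment loading α_t mirrors the strong empirical association
between supplementation and outcome availability in facility-based data
collection; it is what makes complete-case analysis biased *on the treatment
coefficient* (selection that ignores treatment would only shift the
intercept). At the defaults, complete-case estimates center near 23–27 g
against the true 50 g.

RNG contract: one master seed; named sub-streams (treatment, distance,
knowledge, outcome noise, selection noise, MAR mask) are derived through
`numpy.random.SeedSequence` spawn keys, so switching MAR for MNAR does not
perturb the cohort draw. Replicate seeds in the Monte-Carlo engine derive
from (base_seed, replicate, purpose), so any subset of replicates is
reproducible independently and execution order is irrelevant.

What the generator does *not* emulate: covariate-dependent treatment
assignment (no confounding), clustered/village structure, non-normal
residuals, missingness in covariates, or multiple incomplete variables.
Passing tests therefore demonstrate correctness of the estimators under a
correctly specified selection model, not robustness to misspecification on
real data.

## Comparison methods

* **Mean imputation** fills with the overall observed mean (deflates
  variance, attenuates associations).
* **PIDA** fills deterministically, with no added noise, per the pattern
  rule: observed mean ± 0.5·observed SD, or the subject's own treatment-group
  observed mean. The ±0.5 SD scenarios bracket the group-mean scenario;
  the *signed* order depends on which arm is observed more often (with the
  treated observed more, the −0.5 SD fill raises the estimated gap), so
  tests assert the bracketing, not a signed ordering.
* **MICE** uses Bayesian normal-linear regression imputation: σ² drawn from
  the scaled inverse-χ² posterior, coefficients from their conditional
  normal, missing outcomes from the posterior predictive. With a single
  incomplete variable this is one chained-equations step, and it is a proper
  imputation (between-imputation variance is not understated). Predictive
  mean matching would be the natural extension point if non-normal outcomes
  mattered. Default m = 150; the Monte-Carlo engine and tests use m = 25,
  which leaves the pooled point estimate essentially unchanged and keeps the
  replication study fast.
* **Rubin pooling**: total variance = within + (1 + 1/m)·between, df by the
  standard large-sample formula, t-based intervals (normal when between = 0).

## Monte-Carlo engine and problem sizes

Each replicate draws a fresh cohort (covariates and noise both redrawn),
applies the scenario's missingness, runs the requested estimators and
records the treatment estimate with its Wald 95% CI. Summaries report mean,
SD, bias, RMSE (against the configured true effect, not a complete-data
refit) and CI coverage over converged replicates; an estimator failing on
more than 20% of replicates aborts the run with a diagnostic. The package
defaults to 200 replicates of n = 10,000 — enough for a Monte-Carlo SE of
the mean estimate of about 1 g — with larger runs available through the
`--reps` flag.

## Numerical choices

* Inverse Mills ratio as exp(logφ − logΦ) via `scipy.special.log_ndtr`:
  total on finite reals, relative error < 1e-9 against 60-digit arithmetic
  across [−37, 37].
* Probit fits use statsmodels' Newton solver (gradient tolerance 1e-8,
  max 100 iterations) behind this package's interface; perfect separation is
  detected beforehand and reported with the separating column named.
* Rank checks use a scaled QR; collinear columns are named in the error.
* Marginal effects are *average* marginal effects (mean over the sample),
  the conventional dy/dx reporting; effects-at-means are not provided.
* Wald 95% intervals throughout (estimate ± 1.96·SE).
* Two-step ρ̂ clamp at ±0.99; FIML |ρ̂| > 0.995 is logged as a boundary fit.

## Known limitations

* Consistency of every selection estimator here leans on joint normality;
  copula or semiparametric variants are out of scope.
* No clustered or panel selection structure, no robust/cluster SEs.
* The two-step covariance matrix is not the Heckman-corrected one (FIML is
  the inferential path).
* The LR test of ρ = 0 has limited power when ρ is small: under the default
  generator (ρ ≈ 0.141, n = 10,000) it rejects at the 1% level in roughly
  half the replicates, while holding its nominal level under ρ = 0. Tests
  of the rejection behaviour are therefore frequency-based over replicates.
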