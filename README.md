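# heckmansel

Selection-model toolkit for epidemiological studies in which the outcome is
missing for a non-random subset of subjects — the canonical example being
birth weight, which in low-income settings is recorded only for facility
deliveries. When unmeasured traits (health knowledge, care-seeking behaviour)
drive both the outcome and whether it is observed, complete-case analysis and
standard multiple imputation are biased; Heckman-type selection models can
test for and correct this bias.

The package provides, for analysts working with cohort or surveillance data:

* **Heckman estimators** — the classical two-step correction and
  full-information maximum likelihood (FIML) for continuous outcomes, and a
  bivariate probit with selection for binary outcomes, with a
  likelihood-ratio/Wald test of endogenous selection;
* **comparison methods** — complete-case OLS, mean imputation, MICE
  (Bayesian normal-linear imputation with Rubin pooling), and pattern
  imputation with delta adjustment (PIDA, ±0.5 SD shifts or group means);
* **a synthetic birth-cohort generator** and a Monte-Carlo harness that
  measures bias, RMSE and CI coverage of every estimator under complete-data,
  missing-at-random (MAR) and endogenous-selection (MNAR) regimes.

## Model

Two latent equations for outcome y* and selection propensity s*:

    y*_i = x_i' β + μ_i
    s*_i = z_i' γ + ν_i ,      s_i = 1{s*_i > 0},

with (μ, ν) bivariate normal, sd(μ) = σ, sd(ν) = 1, corr(μ, ν) = ρ, and y
observed only when s = 1. Among observed rows,

    E[y | x, z, s = 1] = x'β + ρσ · λ(z'γ),

where λ(u) = φ(u)/Φ(u) is the inverse Mills ratio. When ρ ≠ 0, OLS on the
observed rows is biased; the two-step estimator adds λ(z'γ̂) from a
first-stage probit as a regressor, and FIML maximizes the exact joint
likelihood. The coefficient ρσ ("lambda") diagnoses selection: its sign is
the direction of selection on unobservables, and the test of ρ = 0 is the
formal check. An exclusion restriction — a covariate in z but not x, here
distance to the nearest facility — makes identification robust.

## Worked example

Simulate a 10,000-birth cohort under endogenous selection (60% of outcomes
observed; supplementation truly raises birth weight by 50 g) and compare the
naive and corrected estimates:

```sh
heckmansel simulate --preset study-mnar --seed 1 --out cohort.csv
heckmansel fit --in cohort.csv --method cca          --out cca.csv
heckmansel fit --in cohort.csv --method heckman_fiml --out fiml.csv
```

The complete-case fit (`cca.csv`) is attenuated toward zero:

    beta:treat   24.50   (se 13.08, 95% CI -1.13 to 50.13)

while the FIML selection model (`fiml.csv`) recovers the truth and flags the
selection:

    beta:treat   48.70   (se 15.11, 95% CI 19.07 to 78.32)
    rho           0.164  (se 0.050)
    sigma       498.56
    lambda       81.55   (se 25.33)

`rho > 0` says subjects with higher unobserved outcome determinants are more
likely to be observed — exactly the mechanism the generator builds in — and
the treatment estimate moves from 24.5 g back to the true 50 g neighbourhood.

The replication engine reproduces the full bias comparison (here 200
replicates; the histogram panels land in `mc-out/panels.png`):

```sh
heckmansel mc --scenario mnar --reps 200 --seed 7 \
    --estimators cca,mice,heckman_fiml --out-dir mc-out
```

Everything is also available as a library (`heckmansel.generate_complete`,
`heckmansel.heckman_fiml`, `heckmansel.run_mc`, ...); see `docs/methods.md`
for the modelling details and design choices.

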