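# survmeta

Model-based meta-analysis (MBMA) of aggregate overall-survival data, built
for the setting where individual patient data are unavailable and the
evidence consists of study-level Kaplan–Meier curves digitized from
publications — here, first-line non-platinum chemotherapy regimens
(gemcitabine + vinorelbine, gemcitabine + docetaxel, gemcitabine alone) for
advanced non-small cell lung cancer.

## The model

Each treatment arm *i* contributes overall-survival observations
Obs<sub>ij</sub> at times t<sub>ij</sub> (months). A parametric proportional-
hazard model describes the curve:

- hazard: h(t) = β₀ (constant), β₀·e^(β₁t) (Gompertz) or β₀·t^β₁ (Weibull)
- survival: S(t) = exp(−Λ(0, t)) with Λ the cumulative hazard
- inter-study variability: β_i = β_typical · exp(Σ_k (COV_ik − COV_ref,k)·θ_k + η_i),
  with η_i ~ N(0, ω²) a log-scale random study effect and study-level
  covariates (median age, % PS 2, ...) entering log-linearly, centered at
  reference values
- residual error: Obs_ij = S(t_ij; β_i) + SE_ij · σ_ε · ε_ij, weighting each
  digitized point by the standard error of its survival probability

The marginal likelihood integrates η out per arm; the integral is Laplace-
approximated at the empirical-Bayes mode (an adaptive Gauss–Hermite mode
exists for verification). Covariates are screened stepwise on drops of the
objective function value (OFV = −2 log L) against χ² thresholds 3.84
(forward, α = 0.05) and 6.63 (backward, α = 0.01). After fitting, each
arm's parameter is corrected back to the reference covariate profile
(β_typical·e^η̂ᵢ), pooled per regimen by DerSimonian–Laird random-effects
meta-analysis, and typical survival summaries with 95% CIs come from Monte
Carlo draws of the parameters. Response and toxicity proportions are pooled
by single-arm random-effects meta-analysis on the logit scale.

Because the underlying digitized curves of the original 17 publications are
not redistributable, the package ships a synthetic-data generator that runs
this exact model forward under the published study conditions (17 studies /
20 arms, per-regimen covariate ranges, published parameter values as truth),
retaining the ground truth for recovery and calibration tests.

## Worked example

Survival summaries under the published final model (constant hazard
β₀ = 0.098/month; age coefficient 0.017 per year centered at 72.5; PS2
coefficient 0.004 per percentage point centered at 14%):

```python
import survmeta as sm

model = sm.PopulationParams(
    spec=sm.HazardModelSpec("constant", 0.098),
    cov_model=sm.CovariateModel((
        sm.CovariateTerm("age", 0.017, 72.5),
        sm.CovariateTerm("ps2_pct", 0.004, 14.0),
    )),
)
for age in (60, 70, 80):
    s = sm.simulate_typical_os(model, {"age": age, "ps2_pct": 14.0})
    print(f"age {age}: MST {s.mst:.1f} months, "
          f"1-year survival {s.surv_pct[12.0]:.1f}%, "
          f"2-year survival {s.surv_pct[24.0]:.1f}%")
```

prints

```
age 60: MST 8.7 months, 1-year survival 38.6%, 2-year survival 14.9%
age 70: MST 7.4 months, 1-year survival 32.4%, 2-year survival 10.5%
age 80: MST 6.2 months, 1-year survival 26.3%, 2-year survival 6.9%
```

i.e. a 20-year age difference costs about 2.5 months of median survival; at
age 80 the model predicts a median survival of 6.2 months and 6.9% two-year
survival. Fitting the model to a synthetic replicate of the study design
recovers the generating truth:

```python
dataset, truth = sm.generate_survival_dataset(sm.GeneratorConfig(seed=11))
fit = sm.fit_model(dataset, family="constant",
                   covariate_terms=("age", "ps2_pct"),
                   covariate_refs={"age": 72.5, "ps2_pct": 14.0})
print(fit.summary())
```

```
Mixed-effects survival meta-model (constant hazard)
arms: 20   observations: 515   OFV: -1981.458
converged: True

parameter              value    RSE%              95% CI
beta0                 0.1021     6.3         0.090-0.115
theta_age             0.0199    43.8         0.003-0.037
theta_ps2_pct         0.0049    48.7         0.000-0.010
omega                 0.1846    16.1         0.126-0.243
sigma_eps             0.7872     3.2         0.738-0.836
```

The full pipeline (simulate/ingest → family comparison → stepwise covariate
selection → diagnostics → subgroup and regimen tables → proportion
meta-analysis) is available from the shell:

```sh
survmeta run --seed 4 --out-dir survmeta_out
```

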