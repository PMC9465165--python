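# Methods

## Model

`survmeta` fits a parametric proportional-hazard meta-model to aggregate
overall-survival data: per-arm Kaplan–Meier survival probabilities digitized
from published figures, together with study-level baseline summaries.

Three hazard time-shapes are supported, each with an initial death risk
β₀ > 0 per month:

| family   | h(t)            | Λ(0, t)                          |
|----------|-----------------|----------------------------------|
| constant | β₀              | β₀·t                             |
| gompertz | β₀·e^(β₁t)      | (β₀/β₁)·(e^(β₁t) − 1)            |
| weibull  | β₀·t^β₁         | (β₀/(β₁+1))·t^(β₁+1), β₁ > −1    |

Survival is S(t) = e^(−Λ(0,t)). Time is months throughout; survival is a
fraction in [0, 1] internally and rendered as percent only in reports.

Arm *i*'s parameter is
β_i = β_typical · exp(Σ_k (COV_ik − REF_k)·θ_k + η_i) with η_i ~ N(0, ω²).
Observations follow the additive, SE-weighted residual model
Obs_ij = S(t_ij; β_i) + SE_ij·σ_ε·ε_ij with ε_ij ~ N(0, 1). σ_ε is treated
as the standard deviation multiplying the SE (not a variance) and is
estimated, not fixed at 1. Predictions are not clipped to [0, 1] inside the
likelihood: the residual model is taken literally, so a small survival value
with a small SE can sit slightly outside the unit interval in simulation.

Assumptions worth stating plainly: the random effect acts only on β₀ (the
shape β₁, where present, is shared); residuals are independent across the
points of a curve, which ignores the serial correlation a digitized KM curve
actually has; and the SE of a digitized probability, where not reported, is
approximated by the binomial rule sqrt(S(1−S)/n) with a floor (default
0.005) so points at S ∈ {0, 1} do not get infinite weight.

## Estimation

The marginal likelihood integrates each unit's η out. The integral is
Laplace-approximated at the empirical-Bayes mode: the unit contributes
l(η̂) + log l''(η̂) − log 4π to the OFV (−2 log marginal likelihood), where
l is the conditional −2 log (likelihood × prior). The mode is found by a
safeguarded analytic Newton iteration (the hazard parameter multiplies the
cumulative hazard, so the first and second derivatives in η are closed
form), falling back to bounded Brent search on ±(6ω + 2) if the curvature
turns non-positive. An adaptive Gauss–Hermite quadrature mode
(`marginal_ofv(..., method="aghq")`) exists for verification; on small
instances Laplace agrees with 64-node quadrature to well under 0.1 OFV
units because each unit carries 12–36 observations and the η-posterior is
close to Gaussian.

Fixed effects are optimized on a transformed scale — log β₀, log ω²,
log σ_ε, identity for β₁ and the θs — with L-BFGS-B and up to 3 seeded
restarts on failure. Two numerical details matter:

- Covariate coefficients are standardized internally (divided by the SD of
  the centered covariate across arms) so the optimizer sees O(1)
  coordinates; results are reported on the natural scale. Without this the
  PS2 coefficient's gradient is ~10³ times β₀'s and the first line search
  overflows.
- The inner η-search is a pure function of the outer parameters (no warm
  starts): a history-dependent objective breaks quasi-Newton line searches.

Convergence tolerance is 1e-12 (relative) on the OFV; the covariance is the
inverse of a central finite-difference Hessian (relative step 1e-4) times 2
(since OFV = −2 log L). RSE% and 95% Wald CIs are reported on the natural
scale via the delta method; ω is reported as a standard deviation, with
SE(ω) = ω·SE(log ω²)/2.

The random effect is grouped per treatment arm by default (multi-arm studies
contribute separate curves); `eta_level="study"` shares one η across a
study's arms. Aggregate-level reporting cannot distinguish the two choices
here, so the fitting unit is exposed as configuration.

## Family comparison

`compare_families` fits all three families without covariates and ranks
them by OFV + 3.84·n_params: a nested one-parameter extension must clear
the χ²(α = 0.05, 1 d.f.) threshold to outrank the constant family,
mirroring the covariate-screening rule. A classical AIC penalty (+2 per
parameter) is also computed and selectable, but is not the default: under a
true constant hazard a one-degree extension beats a +2 penalty whenever its
chance OFV improvement exceeds 2, which happens ~16% of the time per
family, so AIC ranking would reject the true family in roughly one run in
five. Raw-OFV ranking is reported for completeness. Ties go to the smaller
family.

## Covariate screening

Forward inclusion adds, one at a time, the candidate with the largest OFV
drop provided it is ≥ 3.84; backward deletion then removes any term whose
deletion raises the OFV by < 6.63, weakest first, until stable. Candidate
covariates are the study-level summaries (age, % male, % PS 2, % stage IV,
and the three histology percentages as separate continuous terms, since a
joint coding of histology is not identifiable from scalar log-linear
terms). Centering references are frozen at the full-dataset medians before
the first step and stored in the model, so the fitted equation keeps one
fixed form across folds and subsets. One covariate moves per step; ties on
the OFV drop break toward the fixed screening order.

## Diagnostics

- Goodness of fit: population predictions at η = 0, individual predictions
  at η̂, weighted residuals (obs − pred_ind)/(SE·σ̂_ε); one row per point.
- Visual predictive check: the fitted model is simulated at the observed
  design (times, covariates, SEs) — η per arm from N(0, ω̂²), residuals per
  point from N(0, (SE·σ̂_ε)²) — and 2.5/50/97.5 pointwise percentile bands
  are computed across replicates. Simulated values are truncated to [0, 1]
  for plotting only, never for band computation. Band coverage of the
  observed points is reported; for a well-specified model it sits near 0.95.
- Leave-one-out: one refit per held-out study (all arms of a study leave
  together; per-arm folds by flag), with frozen centering references, and a
  min/median/max stability summary per parameter. Non-converging folds are
  flagged, never dropped.

## Subgroups, pooling and Monte Carlo summaries

Each arm's covariate-corrected parameter is β_typical·e^η̂ᵢ — its individual
β divided by its covariate multiplier — with log-scale standard error
sqrt(2/l''(η̂)) from the curvature of the empirical-Bayes objective.
Corrected log-parameters are pooled per regimen by DerSimonian–Laird
random-effects meta-analysis (a single arm passes through with its own
interval).

Typical survival summaries draw parameter vectors from a multivariate
normal on the estimation scale — log β₀ and the θs with the fitted
covariance, respecting positivity — and report the median of draws with a
2.5–97.5 percentile interval for the median survival time and for survival
at 12/24/36 months. 10,000 draws by default. Only parameter uncertainty
enters the default intervals; ω² describes between-study spread, not
uncertainty in the typical value. With zero parameter uncertainty the
summaries collapse to the analytic curve (MST = ln 2 / h for the constant
family). Because the summary is a percentile of a nonlinear transform, it
differs from the plug-in value by up to ~0.2 months / ~1 percentage point
in some cells; the deterministic scenario values quoted in the README are
computed at the point estimates.

Scenario encoding: the "PS 0–1" cohort is a hypothetical arm with 0% of
patients at PS 2, and the "PS 2" cohort one with 100%, at the reference age.

## Proportion meta-analysis

Arm-level (events, total) counts per endpoint (ORR and six grade 3–4
adverse events) are pooled on the logit scale with inverse-variance weights
and DerSimonian–Laird τ²; CIs are back-transformed, which keeps them inside
[0, 100]%. Boundary counts get a 0.5 continuity correction with a warning.
Raw-proportion and Freeman–Tukey transforms, a fixed-effect mode and a REML
τ² (1-D restricted-likelihood maximization) are selectable. Endpoint ×
regimen cells with no counts are absent from the report, not zero.

## Synthetic data

The generator runs the model forward under the published study conditions,
which are its defaults: 17 studies contributing 20 arms (6 GV, 6 GD, 8 G);
per-arm sample sizes and the seven covariates drawn uniformly within the
published per-regimen ranges — preserving the real dataset's confounding,
notably that GV arms enrol the youngest and G arms the oldest cohorts
(`stratify_covariates=False` removes it); truth parameters β₀ = 0.098,
θ_age = 0.017, θ_PS2 = 0.004 centered at 72.5 years / 14%, ω = 0.146,
σ_ε = 0.822; monthly observation grid truncated per arm at a follow-up
horizon drawn uniformly from 12–36 months; SEs by the binomial rule with
the 0.005 floor.

Observations are clipped to [0, 1] only at emission and the truth record
keeps the pre-clip values, so likelihood and residual-calibration tests are
exact. Non-monotone wiggles are left in, mimicking digitization noise;
`read_dataset` repairs them by isotonic clipping (capping each point at the
running minimum) with a warning. Two consequences worth knowing: the
additive residual model produces more non-monotonicity than a real digitized
KM curve would have, and the repair biases re-read curves slightly downward
and shrinks their apparent noise — so recovery and calibration tests score
the in-memory (unrepaired) datasets, and a fit to repaired CSV round-trips
can prefer a mildly increasing hazard shape. What passing tests show is that
the estimation machinery inverts its own generative model at the study's
scale and noise level; they cannot show robustness to features real data
have and the generator does not (serially correlated digitization error,
informative follow-up, non-uniform covariate distributions).

`generate_count_data` draws each arm's endpoint proportion logit-normally
around the regimen truth (published pooled values by default) with SD 0.3 —
mild heterogeneity, chosen so that arm-level spread is visible but pooled
estimates stay identifiable with 6–8 arms — then binomial event counts.

## Pipeline and reproducibility

The CLI stages (simulate, fit, select, vpc, loo, subgroup, meta, report)
hand off through files in the output directory and halt with the stage name
and a partial-bundle manifest on failure. All randomness flows from one
master seed via `numpy.random.SeedSequence` children spawned in a fixed
stage order, so stage-by-stage execution reproduces a full run bit-for-bit.
Every report embeds the resolved configuration.

Problem sizes used by the shipped studies: parameter recovery and
family-selection consistency use 20 replicates of the 20-arm design;
selection operating characteristics use 3–8 replicates (widened to 60 arms
for the power study, since the covariate coefficients are identified
against ω² and gain little from larger arms); calibration checks use one
1000-replicate VPC and 40 pooled-proportion replicates.

## Known limitations

- Aggregate curves only: no censoring indicators, no individual event
  times, no time-varying covariates, no cure-fraction models.
- The Gompertz/Weibull branches are validated against quadrature and
  closed-form oracles, not against published estimates — the constant
  family wins selection on data of this shape, so no fitted shape parameter
  exists to compare against.
- DerSimonian–Laird intervals undercover somewhat at 6–8 arms per regimen;
  the REML option does not fully repair this.
- Ecological inference: covariate effects are estimated across study-level
  medians/percentages and need not equal patient-level effects.
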