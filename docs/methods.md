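# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limits of what the test suite demonstrates.

## 1. The bivariate latent change score model

For one puberty–brain pair per sex group g ∈ {female, male}, with observed
vector (P₁, P₂, M₁, M₂, x₁…x_k):

```
P₂ = P₁ + ΔP            ΔP = α_P + β₁·P₁ + γ₂·M₁ + c_P'x + ζ_P
M₂ = M₁ + ΔM            ΔM = α_M + β₂·M₁ + γ₁·P₁ + c_M'x + ζ_M
P₁ = μ_P + b_P'x + e_P
M₁ = μ_M + b_M'x + e_M
cov(e_P, e_M) = ϕ       cov(ζ_P, ζ_M) = ρ
x ~ (ν, Σ_x) free
```

The wave-2 loadings and the unit path from wave 1 into wave 2 are fixed;
the change factors are latent only in the bookkeeping sense (their
distribution is fully determined by the observed moments).  Internally the
covariate terms use centred covariates, so μ and α are interpretable as the
group mean and mean change; this affects intercepts only, never
covariances, standardised effects, or tests.

**Parameter count and degrees of freedom.** Per group there are 14 scalar
parameters plus 4k covariate loadings, k covariate means and k(k+1)/2
covariate (co)variances — exactly the number of free moments of the
saturated Gaussian model.  With covariates entering both baselines and
both change factors the unconstrained model is therefore a *bijective
reparameterisation of the saturated model*: model df = 0, χ² = 0, CFI = 1,
RMSEA = 0 by construction.  All substantive χ² information lives in the
constrained (equality-tied) refits, whose df equals the number of tied
parameters.  Published analyses of this design often report a nonzero
model df (e.g. 28) because some covariate paths are fixed to zero; which
paths is rarely stated, so this package keeps the fully saturated
covariate entry and documents the df consequence rather than guessing.

**Estimation.**  FIML: rows are grouped by missingness pattern; each
pattern contributes the Gaussian log-density of its observed margin,
evaluated from pattern sufficient statistics (n, mean, scatter), so the
likelihood cost is independent of N.  Because the unconstrained model is
saturated, its FIML MLE is obtained exactly by (i) EM for the saturated
Gaussian moments under arbitrary missingness (tolerance 1e-10 on the
moment change, relative to the covariance scale) and (ii) a closed-form
inverse of the structural parameterisation.  Constrained models are
maximised by L-BFGS-B on the penalised negative log-likelihood
(non-positive-definite trial points get a large finite penalty of order
1e10 so the line search can recover), warm-started from the free solution
with tied parameters averaged, function tolerance 1e-13 (relative),
gradient tolerance 1e-5, up to 5 jittered restarts.  A generic
quasi-Newton path from documented neutral starting values (sample
means/variances, zero regressions and covariances, halved baseline
variances for the change residuals) is retained under
`EstimatorOptions(method="qn")` and is tested to agree with the closed
form to 1e-6 in log-likelihood.

All variables are rescaled internally by their pooled SD (one shared scale
per wave pair, so the level-plus-change decomposition survives) and
estimates are mapped back exactly; this gives affine-equivariance of raw
estimates and scale-invariance of standardised ones.

**Standard errors** come from the inverse of the numerically
differentiated observed information (central differences, relative step
1e-4), per group when no cross-group ties exist (the information is then
block-diagonal).  Standardised-solution SEs use the delta method with a
numerical Jacobian of the standardisation map.  A singular information
matrix flags SEs as unavailable rather than failing the fit.

**Standardisation** follows the common SEM convention: regressions scale
by SD(predictor)/SD(outcome) using model-implied variances (implied
var(ΔP) = var(P₂) − 2cov(P₁,P₂) + var(P₁)); the residual covariances ϕ and
ρ become correlations of their residual terms (ϕ/√(ψ_P ψ_M), ρ/√(ζ_P ζ_M));
means and intercepts divide by the implied SD; residual variances become
unexplained-variance fractions.

**Fit indices.**  χ² = −2(ll_model − ll_saturated); the independence
baseline for CFI fixes all covariances to zero, whose FIML solution
factorises per variable and is closed-form; CFI = 1 − max(χ²_M − df_M, 0)
/ max(χ²_B − df_B, 0) clipped to [0, 1] (0/0 defined as 1); multigroup
RMSEA = √G · √(max(χ² − df, 0)/(df·N_total)), defined as 0 with a warning
at df = 0.

**Inference.**  Δχ² = χ²_constrained − χ²_free referred to χ²(Δdf).
Because the free fit is an exact (closed-form) optimum, Δχ² is nonnegative
up to optimiser tolerance; values in (−0.01, 0) are clipped to zero with a
warning and anything below −0.01 is treated as a failed refit.  The FDR
family is the sixteen sex-difference tests only; within-group effects are
reported at raw p, as is conventional for this design.  p-values are
two-sided Wald (no robust/sandwich correction).

## 2. Synthetic cohort generator

The generator draws from the BLCS process itself, so `implied_moments` is
an exact oracle for the pre-rounding, pre-site-effect data.  Default
calibration targets the descriptive anchors of a large two-wave
multi-site adolescent cohort: n = 8896 baseline subjects, female fraction
4223/8896, retention 6099/8896, 21 sites, baseline age 9.9 ± 0.62 years
with a wave gap of 2.0 ± 0.2 years, and sex-specific PDS / FA / MD / CT /
SA means and SDs at both waves.

Choices worth knowing:

- **PDS** is generated as a latent continuous variable, then rounded and
  clamped to the 5–20 total-score range; the downstream model treats it as
  continuous.  The latent mean/SD per sex and wave are solved numerically
  (censored-normal moment equations) so that the *post-clamp* mean and SD
  hit the calibration targets; rounding adds ~1/12 of variance, a ≲1%
  SD inflation that is accepted.
- **Self-feedback** β₁, β₂ are set per variable so the regressed baseline
  carries 75% of the wave-2 SD; the change residual variance is then
  solved to match the wave-2 variance target and is guaranteed positive.
- **Structural defaults** plant the qualitative pattern the package is
  designed to detect, on the standardised scale: female-only γ₁ for
  cortical thickness (−0.08), both-sex γ₁ for surface area (−0.07 female,
  −0.03 male), correlated change in FA (+0.05/+0.03), a male-only baseline
  surface-area correlation (+0.04), γ₂ = 0 everywhere.  Raw values are
  derived from the standardised ones by a small fixed-point iteration
  (γ₁ affects the change SD that standardises it).
- **Covariates**: age, BMI, SES (ordinal 1–10 after rounding) and a
  four-category ancestry label, dummy-coded against the largest category;
  effects on baselines and changes are modest standardised values (see
  `_BASE_COV_EFFECTS`).  Ancestry dummies are generated multinomially and
  enter the Gaussian model through their exact mean/covariance; FIML is
  then quasi-ML with respect to their non-normality, which is standard
  practice.
- **Families**: a configurable fraction of subjects (default 15%) is
  paired into two-child families; siblings share a family-level component
  of the baseline residuals with intraclass correlation 0.3 (marginal
  moments unchanged).  Pairing ignores sex, and mixed-sex siblings are
  generated in separate per-sex passes, so the ICC applies fully only to
  same-sex pairs; `select_unrelated` removes the dependence either way.
- **Attrition** is MAR by default: retention follows a logistic in
  standardised baseline PDS (slope 0.3; slope 0 gives MCAR), with the
  intercept solved by bisection so the marginal retention matches the
  target.  Wave-2 fields of dropped subjects are blanked (monotone
  missingness).
- **Site effects** per feature are additive shifts with SD 0.3 feature-SD
  and log-normal scales (log-SD 0.15), drawn once from a fixed stream so
  defaults are reproducible; they are applied by a separate explicit
  operation and never leak into the clean generator output.
- **Randomness**: one root seed, split into five documented substreams
  (design, covariates, baseline residuals, change residuals, wave gap),
  so generation is a pure function of (config, truth, seed).

What the generator does *not* emulate: item-level PDS questionnaires,
hormone measures, non-linear change, regionally heterogeneous brain
effects, cross-feature residual correlations beyond those induced by the
shared PDS process, and real-world quality-control artefacts.  Passing
tests therefore demonstrate estimator correctness under the stated model,
not robustness to violations of it.

## 3. Longitudinal ComBat

Per feature: a linear mixed model (statsmodels MixedLM, REML, gradient
tolerance 1e-8) with covariates (age, PDS, BMI, SES, ancestry; main
effects only) and sum-to-zero-coded site fixed effects as fixed terms and
a subject random intercept.  Residuals are formed by removing the
covariate fit and the subject BLUP while *leaving the site effect in*,
then standardised by their pooled within-site SD — the pooled-within
choice makes a null batch yield δ̂ ≈ 1 despite BLUP shrinkage of the
residual spread.  Per-site location γ and scale δ are the mean and SD of
the standardised residuals, shrunk by parametric empirical Bayes (normal
prior for γ, inverse-gamma for δ², hyperparameters by method of moments,
standard conditional updates iterated to 1e-8); with only two sites the
moment priors are degenerate and no shrinkage is applied.  The harmonised
value is covariate fit + subject intercept + σ̂·(z − γ̂*)/δ̂*.

Known property: applying the *same* fitted transform twice is not an
identity (an affine per-site map composed with itself is not idempotent
unless it is the identity); what holds, and what is tested, is that
*refitting* on already-harmonised data estimates near-null site effects,
so a second harmonisation pass changes values only within the small
raw-vs-shrunken gap.  The ComBat covariate formula uses main effects only;
interaction or wave terms, and covariance (CovBat-style) harmonisation,
are out of scope.  Rows with missing covariates are excluded from fitting
(counted in the model object) and passed through unharmonised by the
wide-table wrapper.

## 4. Pipeline

Stage order: input (generate or load CSV) → validation (schema, ranges —
PDS ∈ [5, 20], positive ages, cortical thickness 1–5 mm — and a
missingness census) → one-subject-per-family selection → per-feature
harmonisation → four free multigroup fits → sixteen constrained refits →
χ²-difference tests → BH-FDR → report (CSV/JSON, config echo with a hash
of the scientific configuration, harmonisation diagnostics).
Harmonisation is fitted on the post-selection sample by default
(configurable).  Every stage failure aborts with a stage-tagged error.

## 5. Problem sizes used by the test suite

Simulation studies in the suite use sizes chosen to make their Monte-Carlo
error small relative to the tolerance being asserted while keeping the
suite quick: moment-oracle checks at n = 250k draws (4 MC SEs per entry);
parameter recovery and CI coverage at 50 replications of n = 4000/group
(pooled coverage asserted in [90%, 99%]); type-I calibration of the
difference test at 200 replications of n = 800/group (rate asserted within
0.05 ± 0.03); power for a planted γ₁ sex difference of 0.15 SD at 20
replications of n = 3000/group.  All simulations are seeded and therefore
deterministic.

## 6. Known limitations

- Two waves only; no ordinal-PDS estimation; no regional models; no
  non-linear change functions.
- The free model's saturation means CFI/RMSEA are informative only for
  constrained models; published nonzero model dfs for this design cannot
  be reproduced without knowing which covariate paths were fixed.
- Wald SEs and CIs rely on the observed information; no bootstrap or
  sandwich option.
- The MAR attrition model conditions on baseline PDS only.
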