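# blcs-coupling

Longitudinal coupling of pubertal development and brain structure, analysed
with multigroup **bivariate latent change score (BLCS)** models.

The package is aimed at developmental-neuroimaging researchers who want to
ask, with two assessment waves of a large multi-site cohort: do pubertal
status (PDS total score) and a global brain metric (FA, MD, cortical
thickness, surface area) correlate at baseline; does baseline puberty
predict brain *change*; does baseline brain structure predict pubertal
*change*; and do the two changes co-occur — and do any of these couplings
differ between female and male youth?

It provides four things:

1. a **synthetic cohort generator** that emulates the structure of a large
   two-wave adolescent neuroimaging study (≈8,900 children at baseline,
   ≈6,100 at follow-up, 21 acquisition sites, sibling clusters, sex-specific
   PDS distributions, MAR attrition) with a *known* generative BLCS
   parameter set and closed-form implied moments as an oracle;
2. **longitudinal ComBat** harmonisation of multi-site MRI features
   (random subject intercept, covariate-preserving, empirical-Bayes
   shrinkage of per-site location/scale effects);
3. a from-scratch **multigroup BLCS estimator** using full-information
   maximum likelihood (FIML) over missingness patterns, with standard
   errors from the observed information, standardised solutions and
   χ²/CFI/RMSEA fit statistics;
4. **sex-difference inference**: χ²-difference tests of cross-group
   equality constraints, Benjamini–Hochberg FDR over the family of sixteen
   tests (4 metrics × 4 parameters), and a tabular report.

## The model

For each brain metric, wave-2 scores decompose into wave-1 scores plus a
latent change factor, and the two change factors are regressed on both
baseline levels:

```
PDS_t2 = PDS_t1 + ΔPDS          ΔPDS = α_P + β₁·PDS_t1 + γ₂·MRI_t1 + c_P'x + ζ_P
MRI_t2 = MRI_t1 + ΔMRI          ΔMRI = α_M + β₂·MRI_t1 + γ₁·PDS_t1 + c_M'x + ζ_M
```

with baseline covariance `ϕ = cov(PDS_t1, MRI_t1)` (net of covariates),
change residual covariance `ρ = cov(ζ_P, ζ_M)`, covariates `x`
(age, BMI, SES, ancestry dummies) regressed onto both baselines and both
change factors, and every parameter free per sex group unless explicitly
constrained equal.  γ₁ and γ₂ are the *coupling* parameters; ϕ and ρ are
the baseline and correlated-change associations.  Estimation is FIML:
subjects contribute the Gaussian log-density of whatever margin they were
observed on, so follow-up dropouts still inform the baseline structure.

A sex difference in any of (ϕ, γ₁, γ₂, ρ) is tested by refitting with that
parameter tied across groups and referring Δχ² = χ²(constrained) −
χ²(free) to χ² with Δdf degrees of freedom.

## Worked example

```python
from blcs_coupling import (default_config, default_truths, generate_cohort,
                           inject_site_effects, apply_attrition,
                           select_unrelated, harmonize_feature,
                           BLCSSpec, fit)

cfg = default_config(n_baseline=4000, n_sites=6, seed=7)
truths = default_truths(cfg)                  # known generative parameters
cohort = generate_cohort(cfg, truths)
cohort = inject_site_effects(cohort, truths)  # scanner effects to remove
cohort = apply_attrition(cohort, cfg.retention_rate, "MAR", seed=8)
cohort = select_unrelated(cohort, seed=9)     # one subject per family

harmonised, batch = harmonize_feature(cohort, "sa")
spec = BLCSSpec(mri=("sa_t1", "sa_t2"),
                covariates=("age_t1", "bmi", "ses", "ancestry"))
result = fit(spec, harmonised)

print(f"N = {result.n_per_group}, chi2({result.df}) = {result.chisq:.2f}")
for g in result.groups:
    row = {p: (result.std_estimates[g][p], result.std_se[g][p])
           for p in ("phi", "gamma1", "gamma2", "rho")}
    print(g, "  ".join(f"{p}={e:+.3f} (SE {s:.3f})"
                       for p, (e, s) in row.items()))
```

prints

```
N = {'female': 1754, 'male': 1946}, chi2(0) = 0.00
female phi=+0.002 (SE 0.024)  gamma1=-0.060 (SE 0.028)  gamma2=+0.013 (SE 0.028)  rho=-0.051 (SE 0.028)
male phi=+0.015 (SE 0.023)  gamma1=-0.036 (SE 0.028)  gamma2=-0.055 (SE 0.028)  rho=+0.037 (SE 0.028)
```

Reading: the standardised coupling `gamma1` (baseline puberty → surface-area
change) is negative in both sexes and larger in magnitude for females
(−0.060 vs −0.036), matching the generative truth planted by
`default_truths` (−0.07 female, −0.03 male); more pubertally developed
children at baseline show greater surface-area decrease.  The free
multigroup model is saturated under this parameterisation, hence χ²(0) = 0;
the χ² statistics of interest come from the constrained refits.  The full
pipeline — four metrics, sixteen sex-difference tests, FDR — runs with

```
blcs-coupling run --seed 11 --out results/
```

or `run_pipeline(RunConfig(...))` from Python.

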