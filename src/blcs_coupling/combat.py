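"""Longitudinal ComBat harmonisation of multi-site MRI features.

Removes additive (location) and multiplicative (scale) scanner/site effects
from a repeated-measures feature while preserving covariate-associated
biological signal.  The procedure follows the longitudinal variant of
ComBat:

1. fit a linear mixed model (REML) to the long-format feature with the
   biological covariates as fixed effects, site as sum-to-zero-coded fixed
   effects and a subject random intercept;
2. standardise residuals (covariate fit and subject intercept removed,
   site effect left in) by the residual SD;
3. estimate per-site location ``gamma`` and scale ``delta`` on the
   standardised residuals and shrink them across sites by parametric
   empirical Bayes (normal prior for gamma, inverse-gamma prior for
   delta^2, hyperparameters by method of moments);
4. reconstruct the harmonised value as covariate fit + subject intercept +
   rescaled, site-centred residual.

Each feature is harmonised separately.  Rows with missing covariates or
feature values are excluded from fitting (the count is recorded) but can
still be transformed with the fitted effects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model import expand_covariates

__all__ = [
    "BatchModel",
    "to_long",
    "fit_longitudinal_combat",
    "apply_harmonization",
    "site_variance_diagnostic",
    "harmonize_feature",
]


@dataclass
class BatchModel:
    """Everything needed to re-apply a fitted harmonisation to new rows."""

    feature: str
    covariates: list[str]          # original covariate columns
    design_columns: list[str]      # post-expansion numeric design columns
    fixed_effects: dict[str, float]    # intercept + covariate coefficients
    site_levels: list[str]
    subject_intercepts: dict[str, float]
    subject_sd: float
    residual_sd: float
    gamma_raw: dict[str, float]
    delta_raw: dict[str, float]
    gamma_eb: dict[str, float]
    delta_eb: dict[str, float]
    eb_prior: dict[str, float] = field(default_factory=dict)
    eb: bool = True
    n_fit_rows: int = 0
    n_excluded_rows: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=float)

    @classmethod
    def from_json(cls, text: str) -> "BatchModel":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "BatchModel":
        return cls.from_json(Path(path).read_text())


def to_long(table: pd.DataFrame, feature: str,
            covariates: Sequence[str] = ("age", "pds", "bmi", "ses", "ancestry"),
            ) -> pd.DataFrame:
    """Stack a wide two-wave cohort into long format for one feature.

    Wave-varying covariates (age, pds) take their wave's value; one-shot
    covariates (bmi, ses, ancestry) repeat across waves.
    """
    rows = []
    for wave in ("t1", "t2"):
        d = {"subject_id": table["subject_id"], "wave": wave,
             "site_id": table["site_id"],
             "y": table[f"{feature}_{wave}"]}
        for c in covariates:
            wavecol = f"{c}_{wave}"
            d[c] = table[wavecol] if wavecol in table.columns else table[c]
        rows.append(pd.DataFrame(d))
    return pd.concat(rows, ignore_index=True)


def _sum_to_zero_design(site: pd.Series, levels: Sequence[str]) -> np.ndarray:
    """S-1 columns of sum-to-zero (deviation) coding; the last level's
    effect is minus the sum of the others."""
    s = site.astype(str)
    cols = []
    for lev in levels[:-1]:
        col = (s == lev).astype(float) - (s == levels[-1]).astype(float)
        cols.append(col.to_numpy())
    return np.column_stack(cols)


def _eb_hyperparameters(gamma_hat: np.ndarray, delta2_hat: np.ndarray
                        ) -> dict[str, float]:
    """Method-of-moments priors: gamma ~ N(gbar, tau2);
    delta^2 ~ InvGamma(lambda, theta)."""
    gbar = float(np.mean(gamma_hat))
    tau2 = float(np.var(gamma_hat, ddof=1)) if len(gamma_hat) > 1 else 0.0
    m = float(np.mean(delta2_hat))
    v = float(np.var(delta2_hat, ddof=1)) if len(delta2_hat) > 1 else 0.0
    if v > 0:
        lam = (2 * v + m * m) / v
        theta = (m * v + m ** 3) / v
    else:   # degenerate spread: effectively no shrinkage target scale
        lam, theta = 2.0 + m, m * (1.0 + m)
    return {"gamma_bar": gbar, "tau2": tau2, "lambda": lam, "theta": theta}


def _eb_iterate(z_by_site: list[np.ndarray], gamma_hat: np.ndarray,
                delta2_hat: np.ndarray, prior: dict[str, float],
                tol: float = 1e-8, max_iter: int = 200
                ) -> tuple[np.ndarray, np.ndarray]:
    """Standard parametric ComBat conditional EB updates."""
    gbar, tau2 = prior["gamma_bar"], prior["tau2"]
    lam, theta = prior["lambda"], prior["theta"]
    g = gamma_hat.copy()
    d2 = delta2_hat.copy()
    n = np.array([len(z) for z in z_by_site], dtype=float)
    for _ in range(max_iter):
        if tau2 > 0:
            g_new = (n * tau2 * gamma_hat + d2 * gbar) / (n * tau2 + d2)
        else:
            g_new = np.full_like(gamma_hat, gbar)
        ssr = np.array([np.sum((z - gn) ** 2)
                        for z, gn in zip(z_by_site, g_new)])
        d2_new = (theta + 0.5 * ssr) / (n / 2 + lam - 1)
        if (np.abs(g_new - g).max() < tol
                and np.abs(d2_new - d2).max() < tol):
            g, d2 = g_new, d2_new
            break
        g, d2 = g_new, d2_new
    return g, d2


def fit_longitudinal_combat(long_table: pd.DataFrame, feature: str,
                            covariates: Sequence[str] = ("age", "pds", "bmi",
                                                         "ses", "ancestry"),
                            *, eb: bool = True, reml_tol: float = 1e-8
                            ) -> BatchModel:
    """Fit the longitudinal ComBat model on long-format rows.

    ``long_table`` needs columns subject_id, site_id, y, and the covariates.
    Raises if only one site is present ("nothing to harmonise") or if the
    residual variance degenerates to zero.
    """
    levels = sorted(long_table["site_id"].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("single site: nothing to harmonise")

    cov_design, design_cols = expand_covariates(long_table, list(covariates))
    complete = long_table["y"].notna() & cov_design.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    d = long_table.loc[complete].reset_index(drop=True)
    xc = cov_design.loc[complete].to_numpy(dtype=float)

    site_design = _sum_to_zero_design(d["site_id"], levels)
    exog = np.column_stack([np.ones(len(d)), xc, site_design])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixed = sm.MixedLM(d["y"].to_numpy(dtype=float), exog,
                           groups=d["subject_id"].to_numpy())
        res = mixed.fit(reml=True, method="lbfgs",
                        gtol=reml_tol, maxiter=500)
    fe = np.asarray(res.fe_params)
    subj_sd = float(np.sqrt(np.asarray(res.cov_re)[0, 0]))
    re = {str(k): float(np.asarray(v)[0])
          for k, v in res.random_effects.items()}

    # residuals with the site effect left in (covariate fit and subject
    # BLUP removed); standardise by their pooled within-site SD so that a
    # null batch yields delta ~= 1 despite BLUP shrinkage
    fit_cov = fe[0] + xc @ fe[1:1 + xc.shape[1]]
    u = d["subject_id"].astype(str).map(re).to_numpy(dtype=float)
    r = d["y"].to_numpy(dtype=float) - fit_cov - u
    site_str = d["site_id"].astype(str).to_numpy()
    site_means = pd.Series(r).groupby(site_str).transform("mean").to_numpy()
    sigma_e = float(np.sqrt(np.sum((r - site_means) ** 2)
                            / max(len(r) - len(levels), 1)))
    if not np.isfinite(sigma_e) or sigma_e <= 1e-12:
        raise ValueError("zero residual variance; harmonisation undefined")
    z = r / sigma_e
    z_by_site = [z[site_str == lev] for lev in levels]
    if any(len(zz) == 0 for zz in z_by_site):
        raise ValueError("a site has no complete rows")
    gamma_hat = np.array([zz.mean() for zz in z_by_site])
    delta2_hat = np.array([zz.var(ddof=1) if len(zz) > 1 else 1.0
                           for zz in z_by_site])

    prior = _eb_hyperparameters(gamma_hat, delta2_hat)
    if eb and len(levels) > 2:
        gamma_eb, delta2_eb = _eb_iterate(z_by_site, gamma_hat, delta2_hat,
                                          prior)
    else:
        gamma_eb, delta2_eb = gamma_hat.copy(), delta2_hat.copy()

    fixed = {"intercept": float(fe[0])}
    fixed.update({c: float(v) for c, v in zip(design_cols,
                                              fe[1:1 + len(design_cols)])})
    return BatchModel(
        feature=feature, covariates=list(covariates),
        design_columns=design_cols, fixed_effects=fixed,
        site_levels=levels, subject_intercepts=re,
        subject_sd=subj_sd, residual_sd=sigma_e,
        gamma_raw=dict(zip(levels, gamma_hat.tolist())),
        delta_raw=dict(zip(levels, np.sqrt(delta2_hat).tolist())),
        gamma_eb=dict(zip(levels, gamma_eb.tolist())),
        delta_eb=dict(zip(levels, np.sqrt(delta2_eb).tolist())),
        eb_prior=prior, eb=eb,
        n_fit_rows=int(complete.sum()), n_excluded_rows=n_excluded,
    )


def _covariate_fit(model: BatchModel, long_table: pd.DataFrame) -> np.ndarray:
    cov_design, cols = expand_covariates(long_table, model.covariates)
    # align to the columns seen at fit time (unseen dummies get 0)
    x = np.zeros((len(long_table), len(model.design_columns)))
    for j, c in enumerate(model.design_columns):
        if c in cov_design.columns:
            x[:, j] = cov_design[c].to_numpy(dtype=float)
    beta = np.array([model.fixed_effects[c] for c in model.design_columns])
    return model.fixed_effects["intercept"] + x @ beta


def apply_harmonization(model: BatchModel, long_table: pd.DataFrame,
                        *, passthrough_unknown_sites: bool = False
                        ) -> pd.DataFrame:
    """Return ``long_table`` with a harmonised ``y``.

    harmonised y = covariate fit + subject intercept
                   + residual_sd * (z - gamma_site) / delta_site

    where z is the standardised residual.  Subjects unseen at fit time get
    a zero random intercept; unknown sites raise unless
    ``passthrough_unknown_sites`` is set (then rows pass unchanged, with a
    warning).
    """
    site = long_table["site_id"].astype(str)
    known = site.isin(model.site_levels)
    if not known.all():
        if not passthrough_unknown_sites:
            raise ValueError(
                f"unknown site(s) {sorted(site[~known].unique())}; "
                "fit-time sites: " + ",".join(model.site_levels))
        warnings.warn("passing through rows from unknown sites unharmonised",
                      stacklevel=2)
    fit_cov = _covariate_fit(model, long_table)
    u = long_table["subject_id"].astype(str).map(
        model.subject_intercepts).fillna(0.0).to_numpy(dtype=float)
    y = long_table["y"].to_numpy(dtype=float)
    z = (y - fit_cov - u) / model.residual_sd
    g = site.map(model.gamma_eb).to_numpy(dtype=float)
    dl = site.map(model.delta_eb).to_numpy(dtype=float)
    adj = fit_cov + u + model.residual_sd * (z - g) / dl
    out = long_table.copy()
    out["y"] = np.where(known.to_numpy(), adj, y)
    return out


def site_variance_diagnostic(long_table: pd.DataFrame, feature_col: str = "y",
                             site_col: str = "site_id") -> float:
    """Fraction of feature variance explained by site (one-way R^2)."""
    d = long_table[[feature_col, site_col]].dropna()
    sites = d[site_col].unique()
    if len(sites) < 2:
        raise ValueError("single site: diagnostic undefined")
    y = d[feature_col].to_numpy(dtype=float)
    total = ((y - y.mean()) ** 2).sum()
    if total == 0:
        return 0.0
    within = sum(((g - g.mean()) ** 2).sum()
                 for _, g in d.groupby(site_col)[feature_col])
    return float(min(max(1.0 - within / total, 0.0), 1.0))


def harmonize_feature(table: pd.DataFrame, feature: str,
                      covariates: Sequence[str] = ("age", "pds", "bmi",
                                                   "ses", "ancestry"),
                      *, eb: bool = True) -> tuple[pd.DataFrame, BatchModel]:
    """Wide-table convenience wrapper: fit on long format and write the
    harmonised values back into ``<feature>_t1`` / ``<feature>_t2``."""
    long = to_long(table, feature, covariates)
    model = fit_longitudinal_combat(long, feature, covariates, eb=eb)
    adj = apply_harmonization(model, long)
    out = table.copy()
    for wave in ("t1", "t2"):
        vals = adj.loc[adj["wave"] == wave, "y"].to_numpy()
        mask = adj.loc[adj["wave"] == wave, "y"].notna().to_numpy()
        col = out[f"{feature}_{wave}"].to_numpy(dtype=float).copy()
        col[mask] = vals[mask]
        out[f"{feature}_{wave}"] = col
    return out, model
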