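"""Multigroup bivariate latent change score (BLCS) models fitted by FIML.

A two-wave BLCS decomposes the wave-2 score of each domain as the wave-1
score plus a latent change factor::

    PDS_t2 = PDS_t1 + dPDS        dPDS = a_P + beta1*PDS_t1 + gamma2*MRI_t1 + c_P'x + z_P
    MRI_t2 = MRI_t1 + dMRI        dMRI = a_M + beta2*MRI_t1 + gamma1*PDS_t1 + c_M'x + z_M

with a baseline residual covariance ``phi`` between PDS_t1 and MRI_t1 and a
change residual covariance ``rho`` between the two latent changes.  The
coupling parameters ``gamma1`` (baseline puberty -> brain change) and
``gamma2`` (baseline brain -> puberty change) carry the substantive
questions; ``phi`` and ``rho`` carry the baseline and correlated-change
associations.  Covariates x (age, BMI, SES, ancestry dummies) regress onto
both baseline variables and both change factors and are freely
intercorrelated, which makes the unconstrained single-group model an exact
reparameterisation of the saturated Gaussian model over the observed vector
(PDS_t1, PDS_t2, MRI_t1, MRI_t2, x).

Estimation is full-information maximum likelihood (FIML): rows are grouped
by missingness pattern and each pattern contributes the Gaussian log-density
of its observed margin.  Because the unconstrained model is saturated, its
FIML solution is recovered in closed form from the EM estimate of the
saturated moments; models with cross-group equality constraints are fitted
by quasi-Newton (L-BFGS-B) maximisation warm-started from the unconstrained
solution.  Standard errors come from the inverse of the numerically
differentiated observed information.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "BLCSSpec",
    "EstimatorOptions",
    "BLCSModel",
    "FitResult",
    "Pattern",
    "build_model",
    "group_patterns",
    "fiml_loglik",
    "mvn_em",
    "fit",
    "standardize",
    "fit_indices",
    "cfi",
    "rmsea",
    "expand_covariates",
]

_LOG2PI = math.log(2.0 * math.pi)

#: scalar parameters of one group, in canonical order
SCALAR_PARAMS = (
    "mu_pds", "mu_mri", "alpha_pds", "alpha_mri",
    "beta1", "beta2", "gamma1", "gamma2",
    "phi", "rho",
    "psi_pds", "psi_mri", "zeta_pds", "zeta_mri",
)
#: labels admissible in BLCSSpec.constraints
CONSTRAINT_VOCABULARY = frozenset(SCALAR_PARAMS)


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass
class BLCSSpec:
    """Declarative description of one multigroup BLCS model.

    Parameters
    ----------
    pds, mri:
        (wave-1, wave-2) column-name pairs for the puberty score and the
        brain metric.
    group:
        Column holding the two-level grouping variable (sex).
    covariates:
        Covariate columns; categorical columns are dummy-expanded with the
        most frequent level as reference.
    constraints:
        Parameter labels (from :data:`CONSTRAINT_VOCABULARY`) forced equal
        across groups.
    """

    pds: tuple[str, str] = ("pds_t1", "pds_t2")
    mri: tuple[str, str] = ("fa_t1", "fa_t2")
    group: str = "sex"
    covariates: tuple[str, ...] = ()
    constraints: tuple[str, ...] = ()
    groups: tuple[str, str] = ("female", "male")

    def __post_init__(self) -> None:
        names = [*self.pds, *self.mri, *self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("variable names in a BLCSSpec must be distinct")
        bad = set(self.constraints) - CONSTRAINT_VOCABULARY
        if bad:
            raise ValueError(
                f"unknown constraint label(s) {sorted(bad)}; "
                f"allowed: {sorted(CONSTRAINT_VOCABULARY)}"
            )


@dataclass
class EstimatorOptions:
    max_iter: int = 1000
    tol: float = 1e-9              # relative loglik / EM moment tolerance
    gtol: float = 1e-5
    n_starts: int = 5              # jittered restarts for constrained fits
    compute_se: bool = True
    min_group_n: int = 50
    method: str = "auto"           # "auto" (closed form when possible) or "qn"
    seed: int = 0                  # jitter stream for restarts


# ---------------------------------------------------------------------------
# missingness patterns
# ---------------------------------------------------------------------------

@dataclass
class Pattern:
    """Sufficient statistics of one missingness pattern.

    ``observed`` indexes the observed variables; ``mean`` and ``scatter``
    are the sample mean and ML (divide-by-n) covariance of the observed
    margin over the ``n`` rows sharing the pattern.
    """

    observed: np.ndarray   # int index into the variable vector
    n: int
    mean: np.ndarray
    scatter: np.ndarray


def group_patterns(data: np.ndarray) -> list[Pattern]:
    """Group rows of ``data`` (NaN = missing) into missingness patterns."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (rows x variables)")
    mask = ~np.isnan(data)
    if not mask.any(axis=1).all():
        raise ValueError("every row must have at least one observed variable")
    patterns: list[Pattern] = []
    codes = mask.dot(1 << np.arange(mask.shape[1]))
    for code in np.unique(codes):
        rows = data[codes == code]
        obs = np.flatnonzero(mask[codes == code][0])
        y = rows[:, obs]
        m = y.mean(axis=0)
        d = y - m
        patterns.append(Pattern(observed=obs, n=len(y), mean=m,
                                scatter=d.T @ d / len(y)))
    return patterns


def fiml_loglik(mu: np.ndarray, sigma: np.ndarray,
                patterns: Sequence[Pattern]) -> float:
    """Gaussian log-likelihood of pattern-grouped data at (mu, sigma).

    Each missingness pattern contributes the log-density of its observed
    margin; on complete data this reduces to the standard Wishart-form ML
    discrepancy.  Raises ``linalg.LinAlgError`` if a marginal covariance is
    not positive definite.
    """
    total = 0.0
    for pat in patterns:
        o = pat.observed
        s = sigma[np.ix_(o, o)]
        c, low = linalg.cho_factor(s, lower=True)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        inv_scatter = linalg.cho_solve((c, low), pat.scatter)
        dev = pat.mean - mu[o]
        maha = dev @ linalg.cho_solve((c, low), dev)
        total += -0.5 * pat.n * (len(o) * _LOG2PI + logdet
                                 + np.trace(inv_scatter) + maha)
    return float(total)


def mvn_em(patterns: Sequence[Pattern], *, max_iter: int = 500,
           tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Saturated Gaussian MLE under arbitrary missingness by EM.

    Returns ``(mean, cov, loglik, converged)``.  With complete data the
    first iteration already lands on the closed-form MLE.
    """
    p = 1 + max(int(pat.observed.max()) for pat in patterns)
    n_total = sum(pat.n for pat in patterns)
    # available-case start
    mu = np.zeros(p)
    var = np.ones(p)
    counts = np.zeros(p)
    for pat in patterns:
        counts[pat.observed] += pat.n
        mu[pat.observed] += pat.n * pat.mean
    if (counts == 0).any():
        raise ValueError("some variable is never observed")
    mu /= counts
    for pat in patterns:
        o = pat.observed
        var[o] += pat.n * (np.diag(pat.scatter) + (pat.mean - mu[o]) ** 2)
    var = np.maximum((var - 1.0) / counts, 1e-12)
    sigma = np.diag(var)

    converged = False
    for _ in range(max_iter):
        t1 = np.zeros(p)
        t2 = np.zeros((p, p))
        for pat in patterns:
            o = pat.observed
            m = np.setdiff1d(np.arange(p), o, assume_unique=True)
            n = pat.n
            sum_o = n * pat.mean
            ss_oo = n * (pat.scatter + np.outer(pat.mean, pat.mean))
            t1[o] += sum_o
            t2[np.ix_(o, o)] += ss_oo
            if len(m):
                s_oo = sigma[np.ix_(o, o)]
                b = linalg.solve(s_oo, sigma[np.ix_(o, m)],
                                 assume_a="pos").T        # (m, o)
                cond = sigma[np.ix_(m, m)] - b @ sigma[np.ix_(o, m)]
                dev = pat.mean - mu[o]
                e_m = mu[m] + b @ dev                     # mean of E[y_m]
                t1[m] += n * e_m
                # sum_i y_o E[y_m|y_o]' = n ybar mu_m' + n (S + ybar dev') B'
                cross = (n * np.outer(pat.mean, mu[m])
                         + n * (pat.scatter + np.outer(pat.mean, dev)) @ b.T)
                t2[np.ix_(o, m)] += cross
                t2[np.ix_(m, o)] += cross.T
                smm = (n * np.outer(e_m, e_m)
                       + n * b @ pat.scatter @ b.T
                       + n * cond)
                t2[np.ix_(m, m)] += smm
        mu_new = t1 / n_total
        sigma_new = t2 / n_total - np.outer(mu_new, mu_new)
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
        delta = max(np.abs(mu_new - mu).max(),
                    np.abs(sigma_new - sigma).max())
        scale = max(1.0, np.abs(sigma_new).max())
        mu, sigma = mu_new, sigma_new
        if delta < tol * scale:
            converged = True
            break
    ll = fiml_loglik(mu, sigma, patterns)
    return mu, sigma, ll, converged


# ---------------------------------------------------------------------------
# structural parameterisation
# ---------------------------------------------------------------------------

class BLCSModel:
    """Structural matrices and parameter bookkeeping for one BLCSSpec.

    Observed-variable order is (PDS_t1, PDS_t2, MRI_t1, MRI_t2, x_1..x_k).
    Per group the free parameters are the 14 scalars in
    :data:`SCALAR_PARAMS` plus covariate loadings onto the baselines
    (``b_pds``, ``b_mri``) and the change factors (``c_pds``, ``c_mri``),
    covariate means ``nu`` and the covariate covariance ``sigma_x``.
    Constrained labels share one underlying free value across groups.
    """

    def __init__(self, spec: BLCSSpec, covariate_names: Sequence[str]):
        self.spec = spec
        self.covariate_names = list(covariate_names)
        k = len(self.covariate_names)
        self.k = k
        self.n_obs_vars = 4 + k
        names = list(SCALAR_PARAMS)
        for block in ("b_pds", "b_mri", "c_pds", "c_mri", "nu"):
            names += [f"{block}[{c}]" for c in self.covariate_names]
        tri = np.tril_indices(k)
        names += [f"sigma_x[{self.covariate_names[i]},{self.covariate_names[j]}]"
                  for i, j in zip(*tri)]
        self.group_param_names = names
        self.n_group_params = len(names)

        # free-vector layout with cross-group ties
        self.groups = list(spec.groups)
        shared: dict[str, int] = {}
        self.index: list[np.ndarray] = []
        free_names: list[str] = []
        for g in self.groups:
            idx = np.empty(self.n_group_params, dtype=int)
            for j, nm in enumerate(names):
                if nm in spec.constraints:
                    if nm not in shared:
                        shared[nm] = len(free_names)
                        free_names.append(nm)
                    idx[j] = shared[nm]
                else:
                    idx[j] = len(free_names)
                    free_names.append(f"{nm}@{g}")
            self.index.append(idx)
        self.free_names = free_names
        self.n_free = len(free_names)

    # -- packing ------------------------------------------------------------

    def group_vector(self, theta_free: np.ndarray, g: int) -> np.ndarray:
        return np.asarray(theta_free, dtype=float)[self.index[g]]

    def pack(self, group_vectors: Sequence[np.ndarray]) -> np.ndarray:
        """Free vector from per-group vectors (tied entries averaged)."""
        out = np.zeros(self.n_free)
        count = np.zeros(self.n_free)
        for g, vec in enumerate(group_vectors):
            np.add.at(out, self.index[g], vec)
            np.add.at(count, self.index[g], 1.0)
        return out / count

    def split(self, vec: np.ndarray) -> dict[str, np.ndarray | float]:
        """Decompose one group vector into named parts."""
        k = self.k
        d: dict[str, np.ndarray | float] = {
            nm: vec[i] for i, nm in enumerate(SCALAR_PARAMS)}
        pos = len(SCALAR_PARAMS)
        for block in ("b_pds", "b_mri", "c_pds", "c_mri", "nu"):
            d[block] = vec[pos:pos + k]
            pos += k
        sx = np.zeros((k, k))
        tri = np.tril_indices(k)
        sx[tri] = vec[pos:]
        sx = sx + np.tril(sx, -1).T
        d["sigma_x"] = sx
        return d

    def join(self, parts: Mapping[str, np.ndarray | float]) -> np.ndarray:
        k = self.k
        vec = np.empty(self.n_group_params)
        for i, nm in enumerate(SCALAR_PARAMS):
            vec[i] = float(parts[nm])
        pos = len(SCALAR_PARAMS)
        for block in ("b_pds", "b_mri", "c_pds", "c_mri", "nu"):
            vec[pos:pos + k] = np.asarray(parts[block], dtype=float).reshape(k)
            pos += k
        sx = np.asarray(parts["sigma_x"], dtype=float).reshape(k, k)
        vec[pos:] = sx[np.tril_indices(k)]
        return vec

    # -- implied moments ----------------------------------------------------

    def implied_moments(self, group_vec: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Model-implied mean and covariance of (P1, P2, M1, M2, x)."""
        d = self.split(np.asarray(group_vec, dtype=float))
        k = self.k
        b_p, b_m = d["b_pds"], d["b_mri"]
        c_p, c_m = d["c_pds"], d["c_mri"]
        beta1, beta2 = d["beta1"], d["beta2"]
        gamma1, gamma2 = d["gamma1"], d["gamma2"]
        # base vector u = (x, e_p, e_m, z_p, z_m)
        nu_u = k + 4
        L = np.zeros((4 + k, nu_u))
        row_p1 = np.concatenate([b_p, [1.0, 0.0, 0.0, 0.0]])
        row_m1 = np.concatenate([b_m, [0.0, 1.0, 0.0, 0.0]])
        row_dp = np.concatenate([c_p + beta1 * b_p + gamma2 * b_m,
                                 [beta1, gamma2, 1.0, 0.0]])
        row_dm = np.concatenate([c_m + gamma1 * b_p + beta2 * b_m,
                                 [gamma1, beta2, 0.0, 1.0]])
        L[0] = row_p1
        L[1] = row_p1 + row_dp
        L[2] = row_m1
        L[3] = row_m1 + row_dm
        L[4:, :k] = np.eye(k)
        su = np.zeros((nu_u, nu_u))
        su[:k, :k] = d["sigma_x"]
        su[k:k + 2, k:k + 2] = [[d["psi_pds"], d["phi"]],
                                [d["phi"], d["psi_mri"]]]
        su[k + 2:, k + 2:] = [[d["zeta_pds"], d["rho"]],
                              [d["rho"], d["zeta_mri"]]]
        sigma = L @ su @ L.T
        sigma = 0.5 * (sigma + sigma.T)
        mu = np.concatenate([
            [d["mu_pds"], d["mu_pds"] + d["alpha_pds"],
             d["mu_mri"], d["mu_mri"] + d["alpha_mri"]],
            d["nu"]])
        return mu, sigma

    def loglik(self, theta_free: np.ndarray,
               pattern_sets: Sequence[Sequence[Pattern]]) -> float:
        total = 0.0
        for g in range(len(self.groups)):
            mu, sigma = self.implied_moments(self.group_vector(theta_free, g))
            total += fiml_loglik(mu, sigma, pattern_sets[g])
        return total

    def penalized_negloglik(self, theta_free: np.ndarray,
                            pattern_sets: Sequence[Sequence[Pattern]]) -> float:
        """Negative loglik with a large finite penalty for non-PSD points.

        Keeps quasi-Newton iterations recoverable when a trial step leaves
        the admissible region.
        """
        try:
            return -self.loglik(theta_free, pattern_sets)
        except (linalg.LinAlgError, np.linalg.LinAlgError, ValueError):
            worst = 0.0
            for g in range(len(self.groups)):
                _, sigma = self.implied_moments(
                    self.group_vector(theta_free, g))
                w = np.linalg.eigvalsh(sigma).min()
                worst = min(worst, w)
            return 1e10 * (1.0 + abs(worst))

    # -- closed-form solve from saturated moments ---------------------------

    def solve_from_moments(self, mean: np.ndarray, cov: np.ndarray
                           ) -> np.ndarray:
        """Exact per-group MLE from saturated moments (bijection inverse)."""
        k = self.k
        xi = np.arange(4, 4 + k)
        sxx = cov[np.ix_(xi, xi)]
        def xsolve(rhs):
            if k == 0:
                return np.zeros(0)
            return linalg.solve(sxx, rhs, assume_a="pos")
        b_p = xsolve(cov[xi, 0])
        b_m = xsolve(cov[xi, 2])
        psi_p = cov[0, 0] - cov[0, xi] @ b_p
        psi_m = cov[2, 2] - cov[2, xi] @ b_m
        phi = cov[0, 2] - cov[0, xi] @ b_m
        # change-score regressions on (P1, M1, x)
        zi = np.concatenate([[0, 2], xi])
        szz = cov[np.ix_(zi, zi)]
        s_dp = cov[zi, 1] - cov[zi, 0]
        s_dm = cov[zi, 3] - cov[zi, 2]
        a_p = linalg.solve(szz, s_dp, assume_a="pos")
        a_m = linalg.solve(szz, s_dm, assume_a="pos")
        var_dp = cov[1, 1] - 2 * cov[0, 1] + cov[0, 0]
        var_dm = cov[3, 3] - 2 * cov[2, 3] + cov[2, 2]
        cov_dpdm = cov[1, 3] - cov[1, 2] - cov[0, 3] + cov[0, 2]
        zeta_p = var_dp - a_p @ s_dp
        zeta_m = var_dm - a_m @ s_dm
        rho = cov_dpdm - a_p @ s_dm
        return self.join({
            "mu_pds": mean[0], "mu_mri": mean[2],
            "alpha_pds": mean[1] - mean[0], "alpha_mri": mean[3] - mean[2],
            "beta1": a_p[0], "gamma2": a_p[1], "c_pds": a_p[2:],
            "gamma1": a_m[0], "beta2": a_m[1], "c_mri": a_m[2:],
            "phi": phi, "rho": rho,
            "psi_pds": psi_p, "psi_mri": psi_m,
            "zeta_pds": zeta_p, "zeta_mri": zeta_m,
            "b_pds": b_p, "b_mri": b_m,
            "nu": mean[xi], "sigma_x": sxx,
        })

    def default_start(self, pattern_sets: Sequence[Sequence[Pattern]]
                      ) -> np.ndarray:
        """Documented starting values: available-case moments for means and
        variances, zeros for regressions and covariances, halved baseline
        variances for the change residuals."""
        vecs = []
        for pats in pattern_sets:
            p = self.n_obs_vars
            mu = np.zeros(p)
            var = np.ones(p)
            cnt = np.zeros(p)
            for pat in pats:
                cnt[pat.observed] += pat.n
                mu[pat.observed] += pat.n * pat.mean
            mu /= np.maximum(cnt, 1)
            acc = np.zeros(p)
            for pat in pats:
                o = pat.observed
                acc[o] += pat.n * (np.diag(pat.scatter)
                                   + (pat.mean - mu[o]) ** 2)
            var = np.maximum(acc / np.maximum(cnt, 1), 1e-6)
            k = self.k
            vecs.append(self.join({
                "mu_pds": mu[0], "mu_mri": mu[2],
                "alpha_pds": mu[1] - mu[0], "alpha_mri": mu[3] - mu[2],
                "beta1": 0.0, "beta2": 0.0, "gamma1": 0.0, "gamma2": 0.0,
                "phi": 0.0, "rho": 0.0,
                "psi_pds": var[0], "psi_mri": var[2],
                "zeta_pds": 0.5 * var[0], "zeta_mri": 0.5 * var[2],
                "b_pds": np.zeros(k), "b_mri": np.zeros(k),
                "c_pds": np.zeros(k), "c_mri": np.zeros(k),
                "nu": mu[4:], "sigma_x": np.diag(var[4:]) if k else np.zeros((0, 0)),
            }))
        return self.pack(vecs)

    def bounds(self) -> list[tuple[float | None, float | None]]:
        lowers: dict[str, float] = {nm: 1e-10 for nm in
                                    ("psi_pds", "psi_mri", "zeta_pds", "zeta_mri")}
        bnds: list[tuple[float | None, float | None]] = []
        for nm in self.free_names:
            base = nm.split("@")[0]
            if base in lowers:
                bnds.append((lowers[base], None))
            elif base.startswith("sigma_x[") and _is_sx_diag(base):
                bnds.append((1e-10, None))
            else:
                bnds.append((None, None))
        return bnds


def _is_sx_diag(name: str) -> bool:
    inner = name[len("sigma_x["):-1]
    a, b = inner.split(",", 1)
    return a == b


def build_model(spec: BLCSSpec,
                covariate_names: Sequence[str] | None = None) -> BLCSModel:
    """Construct the structural matrices / parameter map for ``spec``.

    ``covariate_names`` are the post-expansion (numeric) covariate columns;
    they default to ``spec.covariates`` taken as already numeric.
    """
    if covariate_names is None:
        covariate_names = spec.covariates
    return BLCSModel(spec, covariate_names)


# ---------------------------------------------------------------------------
# covariate expansion
# ---------------------------------------------------------------------------

def expand_covariates(table: pd.DataFrame, covariates: Sequence[str]
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Numeric covariate design: categoricals become dummies with the most
    frequent level as reference.  Returns (frame, column names)."""
    cols = []
    out = {}
    for c in covariates:
        s = table[c]
        if s.dtype.kind in "ifu":
            out[c] = s.astype(float)
            cols.append(c)
        else:
            levels = s.value_counts().index.tolist()
            for lev in levels[1:]:
                nm = f"{c}[{lev}]"
                out[nm] = (s == lev).astype(float).where(s.notna())
                cols.append(nm)
    return pd.DataFrame(out, index=table.index), cols


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, standard errors and fit statistics of one BLCS fit."""

    spec: BLCSSpec
    groups: list[str]
    param_names: list[str]                 # per-group parameter names
    estimates: dict[str, dict[str, float]]     # group -> name -> raw est
    se: dict[str, dict[str, float]]
    std_estimates: dict[str, dict[str, float]]
    std_se: dict[str, dict[str, float]]
    loglik: float
    loglik_saturated: float
    chisq: float
    df: int
    cfi: float
    rmsea: float
    converged: bool
    se_ok: bool
    n_per_group: dict[str, int]
    pattern_census: dict[str, dict[str, int]]
    n_free: int
    data_fingerprint: str = ""

    @property
    def n_total(self) -> int:
        return sum(self.n_per_group.values())

    def z(self, group: str, name: str, standardized: bool = True) -> float:
        est = (self.std_estimates if standardized else self.estimates)[group][name]
        se = (self.std_se if standardized else self.se)[group][name]
        return est / se if se > 0 else math.nan

    def p(self, group: str, name: str, standardized: bool = True) -> float:
        z = self.z(group, name, standardized)
        return float(2.0 * stats.norm.sf(abs(z))) if math.isfinite(z) else math.nan

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for nm in self.param_names:
                se = self.se[g].get(nm, math.nan)
                est = self.estimates[g][nm]
                z = est / se if se and se > 0 else math.nan
                sest = self.std_estimates[g].get(nm, math.nan)
                sse = self.std_se[g].get(nm, math.nan)
                sz = sest / sse if sse and sse > 0 else math.nan
                rows.append({
                    "group": g, "param": nm, "est": est, "se": se, "z": z,
                    "p": 2 * stats.norm.sf(abs(z)) if math.isfinite(z) else math.nan,
                    "std_est": sest, "std_se": sse, "std_z": sz,
                    "std_p": (2 * stats.norm.sf(abs(sz))
                              if math.isfinite(sz) else math.nan),
                })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        d = asdict(self)
        d["spec"] = asdict(self.spec)
        return json.dumps(d, indent=2, default=float)


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = f(x + 2 * ei); fmm = f(x - 2 * ei)
        hess[i, i] = (fpp - 2 * f0 + fmm) / (4 * h[i] * h[i])
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            fa = f(x + ei + ej); fb = f(x + ei - ej)
            fc = f(x - ei + ej); fd = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fa - fb - fc + fd) / (4 * h[i] * h[j])
    return hess


def _column_scales(model: BLCSModel, frames: Sequence[np.ndarray]) -> np.ndarray:
    """One scale per observed variable; wave pairs share a scale so the
    level-plus-change decomposition is preserved."""
    stacked = np.vstack(frames)
    sd = np.array([np.nanstd(stacked[:, j]) for j in range(stacked.shape[1])])
    sd[sd <= 0] = 1.0
    s_p = math.sqrt(max(sd[0] * sd[1], 1e-30))
    s_m = math.sqrt(max(sd[2] * sd[3], 1e-30))
    scales = np.concatenate([[s_p, s_p, s_m, s_m], sd[4:]])
    return scales


def _rescale_group_vector(model: BLCSModel, vec: np.ndarray,
                          scales: np.ndarray) -> np.ndarray:
    """Transform a group vector fitted on data/scales back to raw units."""
    d = model.split(vec)
    s_p, s_m = scales[0], scales[2]
    s_x = scales[4:]
    out = {
        "mu_pds": d["mu_pds"] * s_p, "mu_mri": d["mu_mri"] * s_m,
        "alpha_pds": d["alpha_pds"] * s_p, "alpha_mri": d["alpha_mri"] * s_m,
        "beta1": d["beta1"], "beta2": d["beta2"],
        "gamma1": d["gamma1"] * s_m / s_p, "gamma2": d["gamma2"] * s_p / s_m,
        "phi": d["phi"] * s_p * s_m, "rho": d["rho"] * s_p * s_m,
        "psi_pds": d["psi_pds"] * s_p ** 2, "psi_mri": d["psi_mri"] * s_m ** 2,
        "zeta_pds": d["zeta_pds"] * s_p ** 2, "zeta_mri": d["zeta_mri"] * s_m ** 2,
        "b_pds": d["b_pds"] * s_p / s_x, "b_mri": d["b_mri"] * s_m / s_x,
        "c_pds": d["c_pds"] * s_p / s_x, "c_mri": d["c_mri"] * s_m / s_x,
        "nu": d["nu"] * s_x,
        "sigma_x": d["sigma_x"] * np.outer(s_x, s_x),
    }
    return model.join(out)


def _standardize_group_vector(model: BLCSModel, vec: np.ndarray) -> np.ndarray:
    """Standardised solution for one group.

    Regressions are scaled by SD(predictor)/SD(outcome) using model-implied
    variances (the change factors are latent, so their implied variances are
    used); the residual covariances ``phi`` and ``rho`` become correlations
    of the corresponding residual terms; means and intercepts are divided by
    the implied SD of their variable; residual variances become the
    unexplained variance fraction.
    """
    d = model.split(vec)
    mu, sigma = model.implied_moments(vec)
    sd_p1 = math.sqrt(max(sigma[0, 0], 1e-300))
    sd_m1 = math.sqrt(max(sigma[2, 2], 1e-300))
    var_dp = sigma[1, 1] - 2 * sigma[0, 1] + sigma[0, 0]
    var_dm = sigma[3, 3] - 2 * sigma[2, 3] + sigma[2, 2]
    sd_dp = math.sqrt(max(var_dp, 1e-300))
    sd_dm = math.sqrt(max(var_dm, 1e-300))
    if min(sigma[0, 0], sigma[2, 2], var_dp, var_dm) <= 0:
        raise ValueError("zero implied variance; cannot standardise")
    sd_x = np.sqrt(np.maximum(np.diag(d["sigma_x"]), 1e-300)) \
        if model.k else np.zeros(0)
    denom_x = np.outer(sd_x, sd_x) if model.k else np.zeros((0, 0))
    out = {
        "mu_pds": d["mu_pds"] / sd_p1, "mu_mri": d["mu_mri"] / sd_m1,
        "alpha_pds": d["alpha_pds"] / sd_dp, "alpha_mri": d["alpha_mri"] / sd_dm,
        "beta1": d["beta1"] * sd_p1 / sd_dp,
        "gamma2": d["gamma2"] * sd_m1 / sd_dp,
        "beta2": d["beta2"] * sd_m1 / sd_dm,
        "gamma1": d["gamma1"] * sd_p1 / sd_dm,
        "phi": d["phi"] / math.sqrt(max(d["psi_pds"] * d["psi_mri"], 1e-300)),
        "rho": d["rho"] / math.sqrt(max(d["zeta_pds"] * d["zeta_mri"], 1e-300)),
        "psi_pds": d["psi_pds"] / sigma[0, 0],
        "psi_mri": d["psi_mri"] / sigma[2, 2],
        "zeta_pds": d["zeta_pds"] / var_dp,
        "zeta_mri": d["zeta_mri"] / var_dm,
        "b_pds": d["b_pds"] * sd_x / sd_p1, "b_mri": d["b_mri"] * sd_x / sd_m1,
        "c_pds": d["c_pds"] * sd_x / sd_dp, "c_mri": d["c_mri"] * sd_x / sd_dm,
        "nu": d["nu"] / np.where(sd_x > 0, sd_x, 1.0) if model.k else d["nu"],
        "sigma_x": (d["sigma_x"] / np.where(denom_x > 0, denom_x, 1.0)
                    if model.k else d["sigma_x"]),
    }
    return model.join(out)


def _independence_loglik(patterns: Sequence[Pattern], p: int) -> tuple[float, int]:
    """FIML loglik and parameter count of the independence baseline model.

    Under mutual independence the likelihood factorises over variables, so
    the MLE is the per-variable mean and ML variance of its observed values.
    """
    sums = np.zeros(p); sqs = np.zeros(p); cnt = np.zeros(p)
    for pat in patterns:
        o = pat.observed
        cnt[o] += pat.n
        sums[o] += pat.n * pat.mean
        sqs[o] += pat.n * (np.diag(pat.scatter) + pat.mean ** 2)
    mu = sums / cnt
    var = np.maximum(sqs / cnt - mu ** 2, 1e-12)
    ll = 0.0
    for pat in patterns:
        o = pat.observed
        dev2 = np.diag(pat.scatter) + (pat.mean - mu[o]) ** 2
        ll += -0.5 * pat.n * np.sum(_LOG2PI + np.log(var[o]) + dev2 / var[o])
    return float(ll), 2 * p


def cfi(chisq_m: float, df_m: float, chisq_b: float, df_b: float) -> float:
    """Comparative fit index, clipped to [0, 1]."""
    num = max(chisq_m - df_m, 0.0)
    den = max(chisq_b - df_b, 0.0)
    if den == 0.0:
        return 1.0 if num == 0.0 else 0.0
    return float(min(max(1.0 - num / den, 0.0), 1.0))


def rmsea(chisq: float, df: float, n_total: int, n_groups: int = 1) -> float:
    """Multigroup RMSEA: sqrt(G) * sqrt(max(chisq - df, 0) / (df * N))."""
    if df <= 0:
        warnings.warn("RMSEA undefined at df = 0; returning 0", stacklevel=2)
        return 0.0
    return float(math.sqrt(n_groups)
                 * math.sqrt(max(chisq - df, 0.0) / (df * n_total)))


def fit_indices(fit: "FitResult", baseline_fit: "FitResult | None" = None
                ) -> tuple[float, int, float, float]:
    """(chisq, df, CFI, RMSEA) of a fitted model (baseline already folded in
    at fit time; an explicit independence ``baseline_fit`` overrides it)."""
    if baseline_fit is None:
        return fit.chisq, fit.df, fit.cfi, fit.rmsea
    c = cfi(fit.chisq, fit.df, baseline_fit.chisq, baseline_fit.df)
    r = rmsea(fit.chisq, fit.df, fit.n_total, len(fit.groups))
    return fit.chisq, fit.df, c, r


def fit(spec: BLCSSpec, table: pd.DataFrame,
        options: EstimatorOptions | None = None) -> FitResult:
    """Fit the multigroup BLCS model by FIML.

    The unconstrained model is an exact reparameterisation of the saturated
    Gaussian model, so its FIML solution is taken in closed form from the
    EM saturated-moment estimate; constrained models are maximised by
    L-BFGS-B warm-started there.  Standard errors use the inverse observed
    information (numerical Hessian).  Deterministic given data and options.
    """
    opts = options or EstimatorOptions()
    cov_frame, cov_names = expand_covariates(table, spec.covariates)
    model = build_model(spec, cov_names)
    cols = [*spec.pds, *spec.mri]

    frames, pattern_sets, ns, census = [], [], {}, {}
    glabels = [g for g in spec.groups if (table[spec.group] == g).any()]
    if len(glabels) != len(spec.groups):
        missing = set(spec.groups) - set(glabels)
        raise ValueError(f"groups absent from data: {sorted(missing)}")
    for g in spec.groups:
        sub = table.loc[table[spec.group] == g]
        y = np.column_stack([sub[c].to_numpy(dtype=float) for c in cols])
        if model.k:
            y = np.hstack([y, cov_frame.loc[sub.index].to_numpy(dtype=float)])
        if len(y) < opts.min_group_n:
            raise ValueError(
                f"group {g!r} has {len(y)} rows; floor is {opts.min_group_n}")
        frames.append(y)
        ns[g] = len(y)

    scales = _column_scales(model, frames)
    for g, y in zip(spec.groups, frames):
        pats = group_patterns(y / scales)
        pattern_sets.append(pats)
        census[g] = {"".join("1" if j in pat.observed else "0"
                             for j in range(model.n_obs_vars)): pat.n
                     for pat in pats}

    # saturated fit per group (EM; closed form on complete data)
    ll_sat = 0.0
    sat_moments = []
    em_ok = True
    for pats in pattern_sets:
        mu, sig, ll, conv = mvn_em(pats, tol=opts.tol)
        em_ok = em_ok and conv
        ll_sat += ll
        sat_moments.append((mu, sig))

    start = model.pack([model.solve_from_moments(mu, sig)
                        for mu, sig in sat_moments])

    constrained = len(spec.constraints) > 0
    if not constrained and opts.method != "qn":
        theta = start
        ll = model.loglik(theta, pattern_sets)
        converged = em_ok
    else:
        theta0 = start if opts.method != "qn" or constrained \
            else model.default_start(pattern_sets)
        rng = np.random.default_rng(opts.seed)
        best = None
        for trial in range(max(1, opts.n_starts)):
            x0 = theta0 if trial == 0 else theta0 * (
                1 + 0.05 * rng.standard_normal(model.n_free))
            res = optimize.minimize(
                model.penalized_negloglik, x0, args=(pattern_sets,),
                method="L-BFGS-B", bounds=model.bounds(),
                options={"maxiter": opts.max_iter,
                         # scipy's ftol is relative to |f|; keep it far
                         # below the loglik scale so restarts agree to 1e-6
                         "ftol": min(opts.tol, 1e-13),
                         "gtol": opts.gtol, "maxfun": 10 * opts.max_iter
                                                      * max(model.n_free, 10)})
            if best is None or res.fun < best.fun:
                best = res
            if best.success and trial == 0:
                break
        theta = best.x
        ll = -best.fun
        converged = bool(best.success) and em_ok

    # degrees of freedom
    p = model.n_obs_vars
    n_sat = len(spec.groups) * (p + p * (p + 1) // 2)
    df = n_sat - model.n_free
    chisq = max(2.0 * (ll_sat - ll), 0.0)

    # baseline (independence) model for CFI
    ll_b, nb = 0.0, 0
    for pats in pattern_sets:
        l, npar = _independence_loglik(pats, p)
        ll_b += l
        nb += npar
    chisq_b = max(2.0 * (ll_sat - ll_b), 0.0)
    df_b = n_sat - nb

    n_total = sum(ns.values())
    cfi_v = cfi(chisq, df, chisq_b, df_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rmsea_v = rmsea(chisq, df, n_total, len(spec.groups))

    # standard errors via observed information on the scaled free vector
    se_free = np.full(model.n_free, math.nan)
    std_cov = None
    se_ok = False
    if opts.compute_se:
        try:
            if not constrained:
                # block-diagonal information: one Hessian per group
                cov_free = np.zeros((model.n_free, model.n_free))
                for g, pats in enumerate(pattern_sets):
                    idx = model.index[g]
                    def fg(v, _g=g, _pats=pats):
                        t = theta.copy()
                        t[model.index[_g]] = v
                        mu, s = model.implied_moments(v)
                        try:
                            return -fiml_loglik(mu, s, _pats)
                        except (linalg.LinAlgError, ValueError):
                            return 1e10
                    h = _numerical_hessian(fg, theta[idx])
                    cov_free[np.ix_(idx, idx)] = linalg.inv(h)
            else:
                h = _numerical_hessian(
                    lambda v: model.penalized_negloglik(v, pattern_sets), theta)
                cov_free = linalg.inv(h)
            d = np.diag(cov_free)
            if (d > 0).all():
                se_free = np.sqrt(d)
                se_ok = True
                std_cov = cov_free
        except linalg.LinAlgError:
            pass

    # assemble per-group raw + standardised tables in original units
    estimates, ses, std_est, std_ses = {}, {}, {}, {}
    for g_i, g in enumerate(spec.groups):
        vec_scaled = model.group_vector(theta, g_i)
        vec_raw = _rescale_group_vector(model, vec_scaled, scales)
        vec_std = _standardize_group_vector(model, vec_scaled)
        se_scaled = se_free[model.index[g_i]]
        # raw rescaling is linear per coordinate, so SEs scale by |factor|
        factor = _rescale_group_vector(
            model, np.ones(model.n_group_params), scales)
        se_raw = np.abs(factor) * se_scaled
        if se_ok and std_cov is not None:
            jac = _std_jacobian(model, theta, g_i)
            cov_std = jac @ std_cov @ jac.T
            dstd = np.diag(cov_std)
            se_std = np.sqrt(np.where(dstd > 0, dstd, math.nan))
        else:
            se_std = np.full(model.n_group_params, math.nan)
        names = model.group_param_names
        estimates[g] = dict(zip(names, vec_raw))
        ses[g] = dict(zip(names, se_raw))
        std_est[g] = dict(zip(names, vec_std))
        std_ses[g] = dict(zip(names, se_std))

    fp = _fingerprint(frames)
    return FitResult(
        spec=spec, groups=list(spec.groups),
        param_names=list(model.group_param_names),
        estimates=estimates, se=ses,
        std_estimates=std_est, std_se=std_ses,
        loglik=float(ll), loglik_saturated=float(ll_sat),
        chisq=float(chisq), df=int(df), cfi=cfi_v, rmsea=rmsea_v,
        converged=converged, se_ok=se_ok,
        n_per_group=ns, pattern_census=census,
        n_free=model.n_free, data_fingerprint=fp,
    )


def _std_jacobian(model: BLCSModel, theta: np.ndarray, g: int,
                  rel_step: float = 1e-6) -> np.ndarray:
    """d(standardised group vector) / d(free vector), numerically."""
    idx = model.index[g]
    base = theta.copy()
    jac = np.zeros((model.n_group_params, model.n_free))
    f0 = _standardize_group_vector(model, base[idx])
    for pos, j in enumerate(idx):
        h = rel_step * max(1.0, abs(theta[j]))
        tp = base.copy(); tp[j] += h
        tm = base.copy(); tm[j] -= h
        try:
            fp = _standardize_group_vector(model, tp[idx])
            fm = _standardize_group_vector(model, tm[idx])
            jac[:, j] += (fp - fm) / (2 * h)
        except ValueError:
            jac[:, j] = math.nan
    return jac


def _fingerprint(frames: Sequence[np.ndarray]) -> str:
    h = 0
    for y in frames:
        arr = np.nan_to_num(y, nan=-9.999e12)
        h ^= hash((y.shape, arr.tobytes()))
    return f"{h & 0xFFFFFFFFFFFF:012x}"


def standardize(fit_result: FitResult) -> FitResult:
    """Return the fit with standardised estimates populated (already done at
    fit time; provided for API symmetry and input checking)."""
    if not fit_result.converged:
        raise ValueError("cannot standardise a non-converged fit")
    for g in fit_result.groups:
        for nm in ("psi_pds", "psi_mri", "zeta_pds", "zeta_mri"):
            if fit_result.estimates[g][nm] <= 0:
                raise ValueError("zero implied variance; cannot standardise")
    return fit_result
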