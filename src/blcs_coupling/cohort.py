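"""Synthetic two-wave cohort generator with a known BLCS ground truth.

Emulates the statistical structure of a large multi-site developmental
cohort: two assessment waves roughly two years apart, a caregiver-report
pubertal development scale (PDS, five items on a 4-point scale, totals in
[5, 20]), four global brain MRI metrics (FA, MD, cortical thickness in mm,
total surface area in cm^2), covariates (age, BMI, SES income band,
a four-category genetic-ancestry label), acquisition-site effects on the
MRI metrics, sibling clusters sharing a family identifier, and follow-up
attrition that may depend on baseline pubertal status (MAR).

The generative process *is* the bivariate latent change score model fitted
downstream, so the model-implied moments are available in closed form as an
oracle (:func:`implied_moments`) and parameter-recovery simulations are
meaningful.  Default calibration reproduces the descriptive anchors of the
cohort the package targets: N = 8896 at baseline with a 4223/4673
female/male split, ~6099 at follow-up, baseline age 9.9 +/- 0.62 years,
sex-specific PDS and MRI distributions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import BLCSSpec, build_model

__all__ = [
    "SexTruth",
    "GroundTruth",
    "CohortConfig",
    "default_config",
    "default_truths",
    "implied_moments",
    "generate_cohort",
    "inject_site_effects",
    "apply_attrition",
    "select_unrelated",
    "write_cohort",
    "read_cohort",
    "FEATURES",
]

FEATURES = ("fa", "md", "ct", "sa")
SEXES = ("female", "male")

#: Descriptive calibration anchors per sex: (mean, sd) at each wave.
#: PDS entries are post-clamp observed-scale targets.
TABLE_CALIBRATION = {
    "female": {
        "age": ((9.9, 0.61), (11.9, 0.63)),
        "pds": ((8.9, 2.59), (12.4, 3.30)),
        "fa": ((0.503, 0.02), (0.510, 0.02)),
        "md": ((0.790, 0.02), (0.786, 0.02)),
        "ct": ((2.73, 0.09), (2.69, 0.09)),
        "sa": ((1813.0, 154.0), (1814.0, 153.0)),
        "bmi": (18.91, 4.23),
        "ses": (7.24, 2.39),
    },
    "male": {
        "age": ((9.9, 0.62), (11.9, 0.64)),
        "pds": ((7.2, 1.86), (8.9, 2.74)),
        "fa": ((0.503, 0.02), (0.509, 0.02)),
        "md": ((0.802, 0.03), (0.792, 0.02)),
        "ct": ((2.72, 0.09), (2.69, 0.09)),
        "sa": ((1977.0, 167.0), (1990.0, 168.0)),
        "bmi": (18.75, 4.03),
        "ses": (7.26, 2.39),
    },
}

#: Standardised structural defaults per feature, mirroring the qualitative
#: result pattern the package is designed to detect: a female-only
#: puberty->thickness coupling, a both-sex (female-stronger) puberty->area
#: coupling, correlated change in FA, and a male-only baseline area
#: correlation.  gamma2 (brain -> puberty-change) is null throughout.
STRUCTURAL_DEFAULTS = {
    #          phi_std        gamma1_std      rho_std
    "fa": {"female": (0.00,  0.00,  0.05), "male": (0.00,  0.00,  0.03)},
    "md": {"female": (0.00,  0.00,  0.00), "male": (0.00,  0.00,  0.00)},
    "ct": {"female": (0.00, -0.08, -0.03), "male": (0.00,  0.00,  0.00)},
    "sa": {"female": (0.00, -0.07,  0.00), "male": (0.04, -0.03,  0.02)},
}

ANCESTRY_LEVELS = ("eur", "afr", "amr", "eas")
ANCESTRY_PROBS = (0.55, 0.20, 0.15, 0.10)

#: covariate columns entering the generative model (ancestry dummy-coded
#: against the largest category)
COVARIATE_NAMES = ("age_t1", "bmi", "ses",
                   "ancestry[afr]", "ancestry[amr]", "ancestry[eas]")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class SexTruth:
    """Generative BLCS parameters for one sex group (one PDS-MRI pair)."""

    mu_pds: float
    mu_mri: float
    alpha_pds: float
    alpha_mri: float
    beta1: float
    beta2: float
    gamma1: float
    gamma2: float
    phi: float
    rho: float
    psi_pds: float
    psi_mri: float
    zeta_pds: float
    zeta_mri: float
    b_pds: np.ndarray
    b_mri: np.ndarray
    c_pds: np.ndarray
    c_mri: np.ndarray
    nu: np.ndarray
    sigma_x: np.ndarray

    def validate(self) -> None:
        for nm in ("psi_pds", "psi_mri", "zeta_pds", "zeta_mri"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")
        if abs(self.phi) > np.sqrt(self.psi_pds * self.psi_mri):
            raise ValueError("phi exceeds its Cauchy-Schwarz bound")
        if abs(self.rho) > np.sqrt(self.zeta_pds * self.zeta_mri):
            raise ValueError("rho exceeds its Cauchy-Schwarz bound")
        sx = np.asarray(self.sigma_x)
        if sx.size and np.linalg.eigvalsh(sx).min() < -1e-10:
            raise ValueError("sigma_x is not positive semi-definite")


@dataclass
class GroundTruth:
    """Generative parameter set for one PDS-MRI pair across both sexes,
    plus the per-site MRI location/scale effects used by
    :func:`inject_site_effects`."""

    feature: str
    covariate_names: tuple[str, ...]
    female: SexTruth
    male: SexTruth
    gamma_site: np.ndarray = field(default_factory=lambda: np.zeros(0))
    delta_site: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def group(self, sex: str) -> SexTruth:
        if sex not in SEXES:
            raise ValueError(f"unknown group {sex!r}")
        return getattr(self, sex)

    def validate(self) -> None:
        for sex in SEXES:
            self.group(sex).validate()
        if len(self.gamma_site) != len(self.delta_site):
            raise ValueError("site effect arrays must have equal length")
        if len(self.delta_site) and (np.asarray(self.delta_site) <= 0).any():
            raise ValueError("site scale effects must be > 0")

    def to_jsonable(self) -> dict:
        def conv(o):
            d = dataclasses.asdict(o)
            return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in d.items()}
        return {"feature": self.feature,
                "covariate_names": list(self.covariate_names),
                "female": conv(self.female), "male": conv(self.male),
                "gamma_site": np.asarray(self.gamma_site).tolist(),
                "delta_site": np.asarray(self.delta_site).tolist()}


@dataclass
class CohortConfig:
    """Simulation design: sample sizes, clustering, sites and attrition."""

    n_baseline: int = 8896
    retention_rate: float = 6099 / 8896
    n_sites: int = 21
    female_fraction: float = 4223 / 8896
    sibling_fraction: float = 0.15   # fraction of subjects with one sampled sibling
    family_icc: float = 0.3          # sibling correlation of baseline residuals
    attrition_mechanism: str = "MAR"
    mar_slope: float = 0.3           # logit slope on standardised baseline PDS
    interwave_years: tuple[float, float] = (2.0, 0.2)
    discretise_scores: bool = True   # round/clamp PDS and SES to their scales
    seed: int = 2023
    calibration: dict = field(default_factory=lambda: TABLE_CALIBRATION)

    def validate(self) -> None:
        if not (0 < self.retention_rate <= 1):
            raise ValueError("retention_rate must be in (0, 1]")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not (0 <= self.sibling_fraction < 1):
            raise ValueError("sibling_fraction must be in [0, 1)")
        if not (0 < self.female_fraction < 1):
            raise ValueError("female_fraction must be in (0, 1)")
        for sex in SEXES:
            for key, val in self.calibration[sex].items():
                sds = [val[1]] if key in ("bmi", "ses") else [val[0][1], val[1][1]]
                if any(s <= 0 for s in sds):
                    raise ValueError(f"calibration SD for {key}/{sex} must be > 0")
        if min(self.n_baseline * self.female_fraction,
               self.n_baseline * (1 - self.female_fraction)) < 2:
            raise ValueError("need at least 2 subjects per sex group")


def default_config(**overrides) -> CohortConfig:
    cfg = CohortConfig(**overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# calibration helpers
# ---------------------------------------------------------------------------

def _clamped_normal_moments(m: float, s: float, lo: float, hi: float
                            ) -> tuple[float, float]:
    """Mean and SD of clamp(N(m, s^2), lo, hi) (two-sided censoring)."""
    a, b = (lo - m) / s, (hi - m) / s
    pa, pb = stats.norm.cdf(a), stats.norm.cdf(b)
    fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
    mid = pb - pa
    e1 = lo * pa + hi * (1 - pb) + m * mid + s * (fa - fb)
    ex2_mid = (m * m + s * s) * mid + 2 * m * s * (fa - fb) \
        + s * s * (a * fa - b * fb)
    e2 = lo * lo * pa + hi * hi * (1 - pb) + ex2_mid
    var = max(e2 - e1 * e1, 1e-12)
    return e1, float(np.sqrt(var))


def _latent_for_clamped_target(mean: float, sd: float,
                               lo: float = 5.0, hi: float = 20.0
                               ) -> tuple[float, float]:
    """Latent normal (mean, sd) whose clamped version matches the target."""
    def eqs(x):
        m, ls = x
        e, s = _clamped_normal_moments(m, np.exp(ls), lo, hi)
        return [e - mean, s - sd]
    sol = optimize.root(eqs, x0=[mean, np.log(sd)], tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"clamp calibration failed for ({mean}, {sd})")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _covariate_distribution(sex: str, calib: Mapping) -> tuple[np.ndarray, np.ndarray]:
    """(nu, sigma_x) over (age, bmi, ses, ancestry dummies)."""
    age_m, age_s = calib[sex]["age"][0]
    bmi_m, bmi_s = calib[sex]["bmi"]
    ses_m, ses_s = calib[sex]["ses"]
    p = np.asarray(ANCESTRY_PROBS[1:])
    nu = np.array([age_m, bmi_m, ses_m, *p])
    sx = np.zeros((6, 6))
    sx[0, 0], sx[1, 1], sx[2, 2] = age_s ** 2, bmi_s ** 2, ses_s ** 2
    sx[3:, 3:] = np.diag(p) - np.outer(p, p)   # multinomial dummy covariance
    return nu, sx


#: modest standardised covariate effects (per covariate SD, in units of the
#: outcome's baseline SD for b_* and of the change SD for c_*); chosen to
#: make covariate handling consequential without dominating the structure
#: fraction of the wave-2 SD carried by the regressed baseline level
_CARRYOVER = 0.75

_BASE_COV_EFFECTS = {
    "pds": {"b": (0.30, 0.15, -0.05, 0.05, 0.03, -0.03),
            "c": (0.10, 0.05, 0.00, 0.00, 0.00, 0.00)},
    "mri": {"b": (0.10, -0.05, 0.05, 0.05, 0.03, 0.02),
            "c": (0.05, 0.00, 0.02, 0.00, 0.00, 0.00)},
}


def _pds_side(sex: str, calib: Mapping) -> dict:
    (m1, s1), (m2, s2) = calib[sex]["pds"]
    mu1, sd1 = _latent_for_clamped_target(m1, s1)
    mu2, sd2 = _latent_for_clamped_target(m2, s2)
    nu, sx = _covariate_distribution(sex, calib)
    sd_x = np.sqrt(np.diag(sx))
    b = np.asarray(_BASE_COV_EFFECTS["pds"]["b"]) * sd1 / sd_x
    # self-feedback chosen so the carried-over baseline contributes 75% of
    # the wave-2 SD, leaving a comfortably positive change residual
    beta1 = _CARRYOVER * sd2 / sd1 - 1.0
    psi = sd1 ** 2 - b @ sx @ b
    if psi <= 0:
        raise ValueError("PDS covariate effects exceed total baseline variance")
    # solve the change residual variance so var(PDS_t2) hits its target:
    # var enters linearly with unit coefficient
    c = np.asarray(_BASE_COV_EFFECTS["pds"]["c"]) * \
        np.sqrt(max(sd2 ** 2 - sd1 ** 2, 0.5 * sd1 ** 2)) / sd_x
    w = (1 + beta1) * b + c
    var_p2_no_zeta = w @ sx @ w + (1 + beta1) ** 2 * psi
    zeta = sd2 ** 2 - var_p2_no_zeta
    if zeta <= 0:
        raise ValueError("implied PDS change variance is non-positive")
    return dict(mu_pds=mu1, alpha_pds=mu2 - mu1, beta1=beta1, psi_pds=psi,
                zeta_pds=zeta, b_pds=b, c_pds=c, nu=nu, sigma_x=sx)


def _feature_truth(feature: str, sex: str, calib: Mapping, pds: dict
                   ) -> SexTruth:
    (m1, s1), (m2, s2) = calib[sex][feature]
    phi_std, gamma1_std, rho_std = STRUCTURAL_DEFAULTS[feature][sex]
    sx = pds["sigma_x"]
    sd_x = np.sqrt(np.diag(sx))
    b = np.asarray(_BASE_COV_EFFECTS["mri"]["b"]) * s1 / sd_x
    c = np.asarray(_BASE_COV_EFFECTS["mri"]["c"]) * \
        0.5 * (s1 + s2) * 0.3 / sd_x
    beta2 = _CARRYOVER * s2 / s1 - 1.0
    psi = s1 ** 2 - b @ sx @ b
    if psi <= 0:
        raise ValueError(f"{feature}: covariate effects exceed baseline variance")
    phi = phi_std * np.sqrt(pds["psi_pds"] * psi)
    sd_p1 = np.sqrt(pds["psi_pds"] + pds["b_pds"] @ sx @ pds["b_pds"])

    # fixed point: gamma1 is specified on the standardised scale, which
    # depends on SD(dMRI), which depends on gamma1 and zeta_mri
    gamma1, zeta = 0.0, 0.25 * s1 ** 2
    for _ in range(60):
        var_dm = _var_dmri(pds, b, c, beta2, gamma1, phi, psi, zeta, sx)
        gamma1_new = gamma1_std * np.sqrt(var_dm) / sd_p1
        w = (1 + beta2) * b + c + gamma1_new * pds["b_pds"]
        var_m2_no_zeta = (w @ sx @ w + (1 + beta2) ** 2 * psi
                          + gamma1_new ** 2 * pds["psi_pds"]
                          + 2 * (1 + beta2) * gamma1_new * phi)
        zeta_new = s2 ** 2 - var_m2_no_zeta
        if zeta_new <= 0:
            raise ValueError(f"{feature}: implied change variance non-positive")
        if abs(gamma1_new - gamma1) < 1e-14 and abs(zeta_new - zeta) < 1e-14:
            gamma1, zeta = gamma1_new, zeta_new
            break
        gamma1, zeta = gamma1_new, zeta_new
    rho = rho_std * np.sqrt(pds["zeta_pds"] * zeta)
    return SexTruth(
        mu_pds=pds["mu_pds"], mu_mri=m1,
        alpha_pds=pds["alpha_pds"], alpha_mri=m2 - m1,
        beta1=pds["beta1"], beta2=beta2, gamma1=gamma1, gamma2=0.0,
        phi=phi, rho=rho,
        psi_pds=pds["psi_pds"], psi_mri=psi,
        zeta_pds=pds["zeta_pds"], zeta_mri=zeta,
        b_pds=pds["b_pds"], b_mri=b, c_pds=pds["c_pds"], c_mri=c,
        nu=pds["nu"], sigma_x=sx,
    )


def _var_dmri(pds, b, c, beta2, gamma1, phi, psi, zeta, sx):
    w = beta2 * b + c + gamma1 * pds["b_pds"]
    return (w @ sx @ w + beta2 ** 2 * psi + gamma1 ** 2 * pds["psi_pds"]
            + 2 * beta2 * gamma1 * phi + zeta)


def default_truths(config: CohortConfig | None = None,
                   site_effect_sd: float = 0.3,
                   site_scale_sd: float = 0.15) -> dict[str, GroundTruth]:
    """Table-calibrated ground truth for all four MRI features.

    Site effects are drawn once from a fixed stream: additive shifts with SD
    ``site_effect_sd`` (in units of the feature SD) and log-normal scale
    factors with log-SD ``site_scale_sd``.
    """
    cfg = config or default_config()
    calib = cfg.calibration
    pds = {sex: _pds_side(sex, calib) for sex in SEXES}
    rng = np.random.default_rng(np.random.SeedSequence([20230607, cfg.n_sites]))
    out = {}
    for feature in FEATURES:
        sd_f = calib["female"][feature][0][1]
        gamma_site = rng.normal(0.0, site_effect_sd * sd_f, cfg.n_sites)
        delta_site = np.exp(rng.normal(0.0, site_scale_sd, cfg.n_sites))
        truth = GroundTruth(
            feature=feature, covariate_names=COVARIATE_NAMES,
            female=_feature_truth(feature, "female", calib, pds["female"]),
            male=_feature_truth(feature, "male", calib, pds["male"]),
            gamma_site=gamma_site, delta_site=delta_site,
        )
        truth.validate()
        out[feature] = truth
    return out


# ---------------------------------------------------------------------------
# implied moments (oracle)
# ---------------------------------------------------------------------------

def implied_moments(truth: GroundTruth, group: str
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form implied mean and covariance over
    (PDS_t1, PDS_t2, MRI_t1, MRI_t2, covariates) for one sex group.

    Follows algebraically from the structural equations with
    ``PDS_t2 = PDS_t1 + dPDS`` and ``MRI_t2 = MRI_t1 + dMRI``.
    """
    truth.validate()
    st = truth.group(group)
    spec = BLCSSpec(mri=(f"{truth.feature}_t1", f"{truth.feature}_t2"),
                    covariates=truth.covariate_names)
    model = build_model(spec, truth.covariate_names)
    vec = model.join(dataclasses.asdict(st))
    mu, sigma = model.implied_moments(vec)
    if np.linalg.eigvalsh(sigma).min() < -1e-8:
        raise ValueError("implied covariance is not PSD")
    return mu, sigma


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _as_truth_map(truth) -> dict[str, GroundTruth]:
    if isinstance(truth, GroundTruth):
        return {truth.feature: truth}
    return dict(truth)


def _check_shared_pds(truths: Mapping[str, GroundTruth]) -> None:
    items = list(truths.values())
    ref = items[0]
    shared = ("mu_pds", "alpha_pds", "beta1", "psi_pds", "zeta_pds")
    for other in items[1:]:
        for sex in SEXES:
            a, b = ref.group(sex), other.group(sex)
            for nm in shared:
                if not np.isclose(getattr(a, nm), getattr(b, nm)):
                    raise ValueError(
                        f"PDS-side parameter {nm} differs between features "
                        f"{ref.feature} and {other.feature}")
            if not (np.allclose(a.b_pds, b.b_pds)
                    and np.allclose(a.c_pds, b.c_pds)):
                raise ValueError("PDS covariate effects differ across features")
    if len(items) > 1 and any(t.group(s).gamma2 != 0.0
                              for t in items for s in SEXES):
        raise ValueError(
            "multi-feature generation requires gamma2 = 0 for every feature "
            "(a shared PDS change equation cannot load on several metrics)")


def generate_cohort(config: CohortConfig,
                    truth: GroundTruth | Mapping[str, GroundTruth]
                    ) -> pd.DataFrame:
    """Draw a two-wave wide-format cohort from the generative BLCS process.

    Deterministic given ``config.seed`` (documented stream split: one child
    seed per stage).  Output has no site effects and no attrition; apply
    :func:`inject_site_effects` and :func:`apply_attrition` explicitly.
    """
    config.validate()
    truths = _as_truth_map(truth)
    for t in truths.values():
        t.validate()
    _check_shared_pds(truths)
    n = config.n_baseline
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_design, rng_cov, rng_base, rng_change, rng_age = \
        (np.random.default_rng(s) for s in streams)

    sex = np.where(rng_design.random(n) < config.female_fraction,
                   "female", "male")
    site = rng_design.integers(1, config.n_sites + 1, size=n)
    # sibling pairs: consecutive subjects merged into one family
    n_pairs = int(n * config.sibling_fraction / 2)
    family = np.arange(n)
    if n_pairs:
        partners = rng_design.choice(n, size=2 * n_pairs, replace=False)
        family[partners[n_pairs:]] = family[partners[:n_pairs]]
    fam_ids = np.array([f"F{f:06d}" for f in family])

    features = list(truths)
    ref = truths[features[0]]
    k = len(ref.covariate_names)
    data = {
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "family_id": fam_ids,
        "sex": sex,
        "site_id": site,
    }
    cols_init = {c: np.empty(n) for c in
                 ("age_t1", "age_t2", "bmi", "ses", "pds_t1", "pds_t2")}
    anc = np.empty(n, dtype=object)
    feat_vals = {f: {w: np.empty(n) for w in ("t1", "t2")} for f in features}

    for s in SEXES:
        idx = np.flatnonzero(sex == s)
        m = len(idx)
        st_ref = ref.group(s)
        nu, sx = st_ref.nu, st_ref.sigma_x
        # covariates: continuous blocks normal, ancestry multinomial
        age = rng_cov.normal(nu[0], np.sqrt(sx[0, 0]), m)
        bmi = rng_cov.normal(nu[1], np.sqrt(sx[1, 1]), m)
        ses = rng_cov.normal(nu[2], np.sqrt(sx[2, 2]), m)
        probs = np.concatenate([[1 - sum(ANCESTRY_PROBS[1:])],
                                ANCESTRY_PROBS[1:]])
        cat = rng_cov.choice(len(ANCESTRY_LEVELS), size=m, p=probs)
        dummies = np.column_stack([(cat == j).astype(float)
                                   for j in range(1, len(ANCESTRY_LEVELS))])
        x = np.column_stack([age, bmi, ses, dummies])
        x_dev = x - nu

        # baseline residuals (e_pds, w_f per feature) with family clustering
        fam_here = family[idx]
        icc = config.family_icc
        n_resid = 1 + len(features)
        uniq, inv = np.unique(fam_here, return_inverse=True)
        fam_draw = rng_base.standard_normal((len(uniq), n_resid))
        ind_draw = rng_base.standard_normal((m, n_resid))
        z = (np.sqrt(icc) * fam_draw[inv] + np.sqrt(1 - icc) * ind_draw)

        e_pds = z[:, 0] * np.sqrt(st_ref.psi_pds)
        p1_dev = x_dev @ st_ref.b_pds + e_pds
        p1 = st_ref.mu_pds + p1_dev

        # change residuals (no family structure on change)
        zeta_draw = rng_change.standard_normal((m, 1 + len(features)))
        z_pds = zeta_draw[:, 0] * np.sqrt(st_ref.zeta_pds)

        gamma2_term = np.zeros(m)
        m1_dev = {}
        for j, f in enumerate(features):
            st = truths[f].group(s)
            # e_mri conditional on e_pds: cov = phi, marginal var = psi_mri
            slope = st.phi / st_ref.psi_pds
            resid_sd = np.sqrt(max(st.psi_mri - st.phi ** 2 / st_ref.psi_pds,
                                   1e-12))
            e_m = slope * e_pds + resid_sd * z[:, 1 + j]
            m1_dev[f] = x_dev @ st.b_mri + e_m
            if st.gamma2 != 0.0:
                gamma2_term = st.gamma2 * m1_dev[f]

        dp = (st_ref.alpha_pds + st_ref.beta1 * p1_dev + gamma2_term
              + x_dev @ st_ref.c_pds + z_pds)
        p2 = p1 + dp

        for j, f in enumerate(features):
            st = truths[f].group(s)
            slope = st.rho / st_ref.zeta_pds
            resid_sd = np.sqrt(max(st.zeta_mri - st.rho ** 2 / st_ref.zeta_pds,
                                   1e-12))
            z_m = slope * z_pds + resid_sd * zeta_draw[:, 1 + j]
            m1 = st.mu_mri + m1_dev[f]
            dm = (st.alpha_mri + st.beta2 * m1_dev[f]
                  + st.gamma1 * p1_dev + x_dev @ st.c_mri + z_m)
            feat_vals[f]["t1"][idx] = m1
            feat_vals[f]["t2"][idx] = m1 + dm

        cols_init["age_t1"][idx] = age
        cols_init["bmi"][idx] = bmi
        cols_init["ses"][idx] = ses
        cols_init["pds_t1"][idx] = p1
        cols_init["pds_t2"][idx] = p2
        anc[idx] = np.asarray(ANCESTRY_LEVELS)[cat]

    gap_mu, gap_sd = config.interwave_years
    cols_init["age_t2"] = cols_init["age_t1"] + rng_age.normal(gap_mu, gap_sd, n)

    if config.discretise_scores:
        for c in ("pds_t1", "pds_t2"):
            cols_init[c] = np.clip(np.round(cols_init[c]), 5, 20)
        cols_init["ses"] = np.clip(np.round(cols_init["ses"]), 1, 10)

    data.update(cols_init)
    data["ancestry"] = anc
    for f in features:
        data[f"{f}_t1"] = feat_vals[f]["t1"]
        data[f"{f}_t2"] = feat_vals[f]["t2"]
    order = ["subject_id", "family_id", "sex", "site_id",
             "age_t1", "age_t2", "pds_t1", "pds_t2"]
    order += [f"{f}_{w}" for f in features for w in ("t1", "t2")]
    order += ["bmi", "ses", "ancestry"]
    return pd.DataFrame(data)[order]


# ---------------------------------------------------------------------------
# site effects, attrition, family selection
# ---------------------------------------------------------------------------

def inject_site_effects(table: pd.DataFrame,
                        truth: GroundTruth | Mapping[str, GroundTruth]
                        ) -> pd.DataFrame:
    """Apply per-site location/scale effects to the MRI features:
    ``x -> gamma_site + delta_site * x`` at both waves.  PDS and covariates
    are untouched.  This simulates the scanner-related, non-biological
    variance the harmonisation step must remove."""
    truths = _as_truth_map(truth)
    out = table.copy()
    sites = out["site_id"].to_numpy()
    for f, t in truths.items():
        if len(t.gamma_site) == 0:
            raise ValueError(f"no site effects configured for {f}")
        if sites.min() < 1 or sites.max() > len(t.gamma_site):
            raise ValueError("site_id outside configured site-effect range")
        g = np.asarray(t.gamma_site)[sites - 1]
        d = np.asarray(t.delta_site)[sites - 1]
        for w in ("t1", "t2"):
            out[f"{f}_{w}"] = g + d * out[f"{f}_{w}"].to_numpy()
    return out


def remove_site_effects(table: pd.DataFrame,
                        truth: GroundTruth | Mapping[str, GroundTruth]
                        ) -> pd.DataFrame:
    """Exact inverse of :func:`inject_site_effects` (oracle un-injection)."""
    truths = _as_truth_map(truth)
    out = table.copy()
    sites = out["site_id"].to_numpy()
    for f, t in truths.items():
        g = np.asarray(t.gamma_site)[sites - 1]
        d = np.asarray(t.delta_site)[sites - 1]
        for w in ("t1", "t2"):
            out[f"{f}_{w}"] = (out[f"{f}_{w}"].to_numpy() - g) / d
    return out


def mar_retention_probabilities(pds_t1: np.ndarray, retention_rate: float,
                                slope: float) -> np.ndarray:
    """Logistic retention probabilities with the stated marginal rate.

    p_i = expit(a + slope * z_i) with z the standardised baseline PDS; the
    intercept a is solved numerically so mean(p) = retention_rate.
    """
    z = (pds_t1 - np.nanmean(pds_t1)) / max(np.nanstd(pds_t1), 1e-12)
    if retention_rate >= 1.0:
        return np.ones_like(z)
    def marginal(a):
        return 1 / (1 + np.exp(-(a + slope * z))) - retention_rate
    a = optimize.brentq(lambda a: marginal(a).mean(), -30, 30, xtol=1e-12)
    return 1 / (1 + np.exp(-(a + slope * z)))


def apply_attrition(table: pd.DataFrame, retention_rate: float,
                    mechanism: str = "MAR", *, slope: float = 0.3,
                    seed: int = 0) -> pd.DataFrame:
    """Drop wave-2 data for a random subset of subjects.

    ``mechanism='MCAR'`` retains uniformly; ``mechanism='MAR'`` retains with
    a logistic probability in baseline PDS (slope 0 reproduces MCAR), with
    the marginal retention equal to ``retention_rate``.  Dropped subjects
    keep all wave-1 fields (monotone missingness).
    """
    if not (0 < retention_rate <= 1):
        raise ValueError("retention_rate must be in (0, 1]")
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError(f"unknown attrition mechanism {mechanism!r}")
    if retention_rate == 1.0:
        return table.copy()
    rng = np.random.default_rng(seed)
    n = len(table)
    if mechanism == "MCAR":
        p = np.full(n, retention_rate)
    else:
        p = mar_retention_probabilities(
            table["pds_t1"].to_numpy(dtype=float), retention_rate, slope)
    keep = rng.random(n) < p
    out = table.copy()
    wave2 = [c for c in out.columns if c.endswith("_t2")]
    out.loc[~keep, wave2] = np.nan
    return out


def select_unrelated(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Keep exactly one randomly chosen subject per family_id."""
    if table["family_id"].isna().any():
        raise ValueError("family_id contains missing values")
    rng = np.random.default_rng(seed)
    pick = np.zeros(len(table), dtype=bool)
    order = np.arange(len(table))
    for _, rows in pd.Series(order, index=table["family_id"].to_numpy()
                             ).groupby(level=0, sort=True):
        pick[rng.choice(rows.to_numpy())] = True
    return table.loc[pick].copy()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(table: pd.DataFrame, path: str | Path,
                 config: CohortConfig | None = None,
                 truths: Mapping[str, GroundTruth] | None = None) -> None:
    """CSV with empty-field missing values plus a sidecar JSON recording the
    config, ground truth and seed."""
    path = Path(path)
    table.to_csv(path, index=False, na_rep="")
    meta: dict = {}
    if config is not None:
        meta["config"] = dataclasses.asdict(config)
        meta["seed"] = config.seed
    if truths is not None:
        meta["truth"] = {f: t.to_jsonable() for f, t in truths.items()}
    if meta:
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, default=float))


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "family_id": str,
                                  "sex": str, "ancestry": str})
    return df
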