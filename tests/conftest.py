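"""Shared fixtures: compact ground truths and oracle-driven simulators."""

import numpy as np
import pandas as pd
import pytest

from blcs_coupling.cohort import (CohortConfig, GroundTruth, SexTruth,
                                  default_config, default_truths,
                                  generate_cohort, implied_moments)


def make_sex_truth(*, mu_pds=8.0, mu_mri=0.5, alpha_pds=1.8, alpha_mri=0.01,
                   beta1=-0.1, beta2=-0.2, gamma1=0.0, gamma2=0.0,
                   phi=0.0, rho=0.0, psi_pds=4.0, psi_mri=1.0,
                   zeta_pds=3.0, zeta_mri=0.8, k=0) -> SexTruth:
    """A covariate-free (or k-covariate) single-pair truth for simulations."""
    return SexTruth(
        mu_pds=mu_pds, mu_mri=mu_mri, alpha_pds=alpha_pds,
        alpha_mri=alpha_mri, beta1=beta1, beta2=beta2, gamma1=gamma1,
        gamma2=gamma2, phi=phi, rho=rho, psi_pds=psi_pds, psi_mri=psi_mri,
        zeta_pds=zeta_pds, zeta_mri=zeta_mri,
        b_pds=np.zeros(k), b_mri=np.zeros(k), c_pds=np.zeros(k),
        c_mri=np.zeros(k), nu=np.zeros(k), sigma_x=np.eye(k),
    )


def make_truth(female: SexTruth | None = None, male: SexTruth | None = None,
               feature: str = "fa", covariate_names=()) -> GroundTruth:
    truth = GroundTruth(
        feature=feature, covariate_names=tuple(covariate_names),
        female=female or make_sex_truth(),
        male=male or make_sex_truth(),
    )
    truth.validate()
    return truth


def simulate_from_truth(truth: GroundTruth, n_per_group: int, seed: int,
                        retention: float = 1.0) -> pd.DataFrame:
    """Draw exact multivariate-normal data from the implied moments.

    This is the model's own data-generating process without rounding or
    clamping, suitable for estimator calibration studies; optional MCAR
    wave-2 attrition.
    """
    rng = np.random.default_rng(seed)
    frames = []
    f = truth.feature
    for sex in ("female", "male"):
        mu, sigma = implied_moments(truth, sex)
        y = rng.multivariate_normal(mu, sigma, size=n_per_group,
                                    method="cholesky")
        cols = {"pds_t1": y[:, 0], "pds_t2": y[:, 1],
                f"{f}_t1": y[:, 2], f"{f}_t2": y[:, 3]}
        for j, c in enumerate(truth.covariate_names):
            cols[c] = y[:, 4 + j]
        d = pd.DataFrame(cols)
        d["sex"] = sex
        frames.append(d)
    out = pd.concat(frames, ignore_index=True)
    if retention < 1.0:
        drop = rng.random(len(out)) >= retention
        out.loc[drop, ["pds_t2", f"{f}_t2"]] = np.nan
    return out


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return default_config(n_baseline=1500, n_sites=4, seed=101,
                          sibling_fraction=0.1)


@pytest.fixture(scope="session")
def small_truths(small_config):
    return default_truths(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_truths):
    return generate_cohort(small_config, small_truths)


@pytest.fixture(scope="session")
def default_cohort_8896():
    cfg = default_config(seed=606)
    truths = default_truths(cfg)
    return cfg, truths, generate_cohort(cfg, truths)
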