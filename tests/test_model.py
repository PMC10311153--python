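"""BLCS estimator: structure, FIML likelihood, fitting, standardisation
and fit indices."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from blcs_coupling.model import (BLCSSpec, EstimatorOptions, build_model,
                                 cfi, fiml_loglik, fit, fit_indices,
                                 group_patterns, mvn_em, rmsea, standardize)

from conftest import make_sex_truth, make_truth, simulate_from_truth


def _per_group_count(k: int) -> int:
    """Hand count of the documented parameterisation: 14 scalars
    + 4 covariate-effect blocks + covariate means + covariate covariance."""
    return 14 + 4 * k + k + k * (k + 1) // 2


# ---------------------------------------------------------------------------
# build_model
# ---------------------------------------------------------------------------

class TestBuildModel:
    def test_free_parameter_count_two_groups_four_covariates(self):
        spec = BLCSSpec(covariates=("a", "b", "c", "d"))
        m = build_model(spec)
        assert m.n_free == 2 * _per_group_count(4)

    def test_constraint_reduces_count_by_one(self):
        free = build_model(BLCSSpec())
        tied = build_model(BLCSSpec(constraints=("gamma1",)))
        assert free.n_free - tied.n_free == 1

    def test_unknown_constraint_label_rejected(self):
        with pytest.raises(ValueError, match="constraint"):
            BLCSSpec(constraints=("gamma9",))

    def test_duplicate_variable_names_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            BLCSSpec(pds=("x", "x"))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_implied_covariance_is_psd_at_admissible_points(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(0, 4))
        model = build_model(BLCSSpec(covariates=tuple(
            f"x{i}" for i in range(k))))
        a = rng.standard_normal((k, k))
        psi = rng.uniform(0.2, 3, 2)
        zeta = rng.uniform(0.2, 3, 2)
        parts = {
            "mu_pds": rng.normal(), "mu_mri": rng.normal(),
            "alpha_pds": rng.normal(), "alpha_mri": rng.normal(),
            "beta1": rng.normal(0, 0.5), "beta2": rng.normal(0, 0.5),
            "gamma1": rng.normal(0, 0.5), "gamma2": rng.normal(0, 0.5),
            "phi": rng.uniform(-0.9, 0.9) * np.sqrt(psi[0] * psi[1]),
            "rho": rng.uniform(-0.9, 0.9) * np.sqrt(zeta[0] * zeta[1]),
            "psi_pds": psi[0], "psi_mri": psi[1],
            "zeta_pds": zeta[0], "zeta_mri": zeta[1],
            "b_pds": rng.standard_normal(k), "b_mri": rng.standard_normal(k),
            "c_pds": rng.standard_normal(k), "c_mri": rng.standard_normal(k),
            "nu": rng.standard_normal(k),
            "sigma_x": a @ a.T + 0.1 * np.eye(k),
        }
        _, sigma = model.implied_moments(model.join(parts))
        assert np.allclose(sigma, sigma.T)
        assert np.linalg.eigvalsh(sigma).min() > -1e-10


# ---------------------------------------------------------------------------
# FIML likelihood
# ---------------------------------------------------------------------------

class TestFimlLoglik:
    def test_complete_data_matches_rowwise_density_oracle(self):
        truth = make_truth(make_sex_truth(phi=0.6, rho=0.4))
        tab = simulate_from_truth(truth, 300, seed=9)
        y = tab.loc[tab.sex == "female",
                    ["pds_t1", "pds_t2", "fa_t1", "fa_t2"]].to_numpy()
        mu, sigma = y.mean(0), np.cov(y.T)
        ll = fiml_loglik(mu, sigma, group_patterns(y))
        oracle = stats.multivariate_normal(mu, sigma).logpdf(y).sum()
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_saturated_chisq_is_zero(self):
        truth = make_truth()
        tab = simulate_from_truth(truth, 400, seed=10)
        res = fit(BLCSSpec(), tab, EstimatorOptions(compute_se=False))
        assert res.chisq == pytest.approx(0.0, abs=1e-6)
        assert res.df == 0

    def test_wave1_only_row_adds_its_marginal_density(self):
        """Appending a subject observed only at wave 1 changes the total
        log-likelihood by exactly that subject's bivariate marginal."""
        truth = make_truth()
        tab = simulate_from_truth(truth, 150, seed=11)
        y = tab.loc[tab.sex == "male",
                    ["pds_t1", "pds_t2", "fa_t1", "fa_t2"]].to_numpy()
        mu, sigma = y.mean(0), np.cov(y.T)
        extra = np.array([[7.5, np.nan, 0.45, np.nan]])
        ll_with = fiml_loglik(mu, sigma, group_patterns(np.vstack([y, extra])))
        ll_without = fiml_loglik(mu, sigma, group_patterns(y))
        marginal = stats.multivariate_normal(
            mu[[0, 2]], sigma[np.ix_([0, 2], [0, 2])]
        ).logpdf(extra[0, [0, 2]])
        assert ll_with - ll_without == pytest.approx(marginal, abs=1e-8)

    def test_em_recovers_moments_under_mcar(self):
        truth = make_truth(make_sex_truth(phi=0.8, rho=0.5))
        tab = simulate_from_truth(truth, 4000, seed=12, retention=0.6)
        y = tab.loc[tab.sex == "female",
                    ["pds_t1", "pds_t2", "fa_t1", "fa_t2"]].to_numpy()
        mu, sigma, ll, conv = mvn_em(group_patterns(y))
        assert conv
        from blcs_coupling.cohort import implied_moments
        imp_mu, imp_sig = implied_moments(truth, "female")
        assert np.abs(mu - imp_mu).max() < 4 * np.sqrt(
            np.diag(imp_sig) / 2000).max()


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

class TestFit:
    def test_row_permutation_invariance(self):
        truth = make_truth()
        tab = simulate_from_truth(truth, 500, seed=14)
        res1 = fit(BLCSSpec(), tab, EstimatorOptions(compute_se=False))
        perm = tab.sample(frac=1.0, random_state=5).reset_index(drop=True)
        res2 = fit(BLCSSpec(), perm, EstimatorOptions(compute_se=False))
        for g in res1.groups:
            for nm in res1.param_names:
                assert res1.estimates[g][nm] == pytest.approx(
                    res2.estimates[g][nm], abs=1e-10, rel=1e-9)

    def test_quasi_newton_agrees_with_closed_form(self):
        """The generic optimiser from the documented starting values lands
        on the same optimum as the closed-form saturated solve (5 jittered
        restarts agree within 1e-6 on the log-likelihood)."""
        truth = make_truth(make_sex_truth(gamma1=0.05, phi=0.7, rho=0.3))
        tab = simulate_from_truth(truth, 600, seed=15)
        closed = fit(BLCSSpec(), tab, EstimatorOptions(compute_se=False))
        qn = fit(BLCSSpec(), tab,
                 EstimatorOptions(compute_se=False, method="qn", n_starts=5))
        assert qn.loglik == pytest.approx(closed.loglik, abs=1e-6)

    def test_fiml_equals_complete_data_ml_on_complete_rows(self):
        truth = make_truth(make_sex_truth(phi=0.5))
        tab = simulate_from_truth(truth, 800, seed=16)
        a = fit(BLCSSpec(), tab, EstimatorOptions(compute_se=False))
        b = fit(BLCSSpec(), tab, EstimatorOptions(compute_se=False,
                                                  method="qn"))
        for g in a.groups:
            for nm in ("beta1", "beta2", "gamma1", "gamma2", "phi", "rho"):
                assert a.estimates[g][nm] == pytest.approx(
                    b.estimates[g][nm], abs=5e-4)

    def test_affine_rescaling_equivariance(self):
        """Scaling the MRI variable by 1000 transforms raw estimates per
        the algebra and leaves standardised estimates unchanged."""
        truth = make_truth(make_sex_truth(gamma1=0.03, phi=0.6, rho=0.25))
        tab = simulate_from_truth(truth, 1200, seed=17)
        base = fit(BLCSSpec(), tab, EstimatorOptions(compute_se=False))
        scaled_tab = tab.copy()
        scaled_tab[["fa_t1", "fa_t2"]] = scaled_tab[["fa_t1", "fa_t2"]] * 1e3
        scaled = fit(BLCSSpec(), scaled_tab,
                     EstimatorOptions(compute_se=False))
        for g in base.groups:
            assert scaled.estimates[g]["gamma1"] == pytest.approx(
                base.estimates[g]["gamma1"] * 1e3, rel=1e-7)
            assert scaled.estimates[g]["gamma2"] == pytest.approx(
                base.estimates[g]["gamma2"] / 1e3, rel=1e-7)
            assert scaled.estimates[g]["beta2"] == pytest.approx(
                base.estimates[g]["beta2"], rel=1e-7)
            for nm in ("phi", "rho", "gamma1", "gamma2", "beta1", "beta2"):
                assert scaled.std_estimates[g][nm] == pytest.approx(
                    base.std_estimates[g][nm], abs=1e-8)

    def test_group_floor_enforced(self):
        truth = make_truth()
        tab = simulate_from_truth(truth, 20, seed=18)
        with pytest.raises(ValueError, match="floor"):
            fit(BLCSSpec(), tab)

    def test_null_coupling_z_statistics_are_standard_normal(self):
        """With gamma1 = 0 in truth, the Wald z of gamma1 across seeded
        replications is compatible with N(0, 1) (KS test)."""
        truth = make_truth()
        zs = []
        for rep in range(100):
            tab = simulate_from_truth(truth, 700, seed=1000 + rep)
            r = fit(BLCSSpec(), tab)
            for g in r.groups:
                zs.append(r.estimates[g]["gamma1"] / r.se[g]["gamma1"])
        assert stats.kstest(zs, "norm").pvalue > 0.01


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------

class TestStandardize:
    def test_identity_under_unit_implied_scale(self):
        """When all implied variances are 1, standardised equals raw."""
        st_truth = make_sex_truth(beta1=0, beta2=0, psi_pds=1, psi_mri=1,
                                  zeta_pds=1, zeta_mri=1, phi=0.3, rho=0.2)
        truth = make_truth(st_truth, st_truth)
        tab = simulate_from_truth(truth, 100_000, seed=19)
        r = fit(BLCSSpec(), tab, EstimatorOptions(compute_se=False))
        for nm in ("phi", "rho"):
            assert r.std_estimates["female"][nm] == pytest.approx(
                r.estimates["female"][nm], abs=0.02)

    def test_hand_computed_standardisation(self):
        """Frozen hand calculation: gamma1_std = gamma1 * SD(P1)/SD(dM)
        with var(dM) = gamma1^2 var(P1) + beta2^2 var(M1)
        + 2 beta2 gamma1 phi + zeta_mri (beta-weighted covariances written
        out for the covariate-free model)."""
        model = build_model(BLCSSpec())
        parts = dict(mu_pds=0, mu_mri=0, alpha_pds=0, alpha_mri=0,
                     beta1=-0.2, beta2=-0.4, gamma1=0.3, gamma2=0.0,
                     phi=1.0, rho=0.1, psi_pds=4.0, psi_mri=2.25,
                     zeta_pds=1.0, zeta_mri=1.0,
                     b_pds=np.zeros(0), b_mri=np.zeros(0),
                     c_pds=np.zeros(0), c_mri=np.zeros(0),
                     nu=np.zeros(0), sigma_x=np.zeros((0, 0)))
        vec = model.join(parts)
        from blcs_coupling.model import _standardize_group_vector
        std = model.split(_standardize_group_vector(model, vec))
        var_dm = (0.3 ** 2 * 4.0 + 0.4 ** 2 * 2.25
                  + 2 * (-0.4) * 0.3 * 1.0 + 1.0)
        assert std["gamma1"] == pytest.approx(0.3 * 2.0 / math.sqrt(var_dm))
        assert std["phi"] == pytest.approx(1.0 / math.sqrt(4.0 * 2.25))
        assert std["rho"] == pytest.approx(0.1 / math.sqrt(1.0 * 1.0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_standardised_covariances_are_correlations(self, seed):
        """phi and rho standardise into [-1, 1] for any admissible model."""
        rng = np.random.default_rng(seed)
        model = build_model(BLCSSpec())
        psi = rng.uniform(0.1, 5, 2)
        zeta = rng.uniform(0.1, 5, 2)
        parts = dict(
            mu_pds=rng.normal(), mu_mri=rng.normal(),
            alpha_pds=rng.normal(), alpha_mri=rng.normal(),
            beta1=rng.normal(0, 0.6), beta2=rng.normal(0, 0.6),
            gamma1=rng.normal(0, 0.6), gamma2=rng.normal(0, 0.6),
            phi=rng.uniform(-1, 1) * np.sqrt(psi[0] * psi[1]),
            rho=rng.uniform(-1, 1) * np.sqrt(zeta[0] * zeta[1]),
            psi_pds=psi[0], psi_mri=psi[1],
            zeta_pds=zeta[0], zeta_mri=zeta[1],
            b_pds=np.zeros(0), b_mri=np.zeros(0), c_pds=np.zeros(0),
            c_mri=np.zeros(0), nu=np.zeros(0), sigma_x=np.zeros((0, 0)))
        from blcs_coupling.model import _standardize_group_vector
        std = model.split(_standardize_group_vector(model, model.join(parts)))
        assert -1 <= std["phi"] <= 1
        assert -1 <= std["rho"] <= 1

    def test_nonconverged_fit_rejected(self):
        truth = make_truth()
        tab = simulate_from_truth(truth, 200, seed=21)
        r = fit(BLCSSpec(), tab, EstimatorOptions(compute_se=False))
        r.converged = False
        with pytest.raises(ValueError, match="non-converged"):
            standardize(r)


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

class TestFitIndices:
    def test_multigroup_rmsea_formula(self):
        """chisq=272.45, df=28, N=8896, G=2 gives 0.044, printing as 0.04."""
        v = rmsea(272.45, 28, 8896, 2)
        assert v == pytest.approx(0.0443, abs=5e-4)
        assert round(v, 2) == 0.04

    def test_saturated_model_has_perfect_indices(self):
        truth = make_truth()
        tab = simulate_from_truth(truth, 300, seed=22)
        r = fit(BLCSSpec(), tab, EstimatorOptions(compute_se=False))
        chisq, df, c, rm = fit_indices(r)
        assert c == 1.0
        assert rm == 0.0

    def test_cfi_zero_when_model_no_better_than_baseline(self):
        assert cfi(100.0, 10, 100.0, 10) == 0.0

    def test_rmsea_zero_df_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="df"):
            assert rmsea(5.0, 0, 100, 2) == 0.0

    def test_chisq_mean_tracks_df_for_constrained_true_model(self):
        """Fitting a true equality constraint yields chi-square values
        averaging about df = 1 across replications."""
        truth = make_truth()   # groups identical, gamma1 equal
        vals = []
        for rep in range(60):
            tab = simulate_from_truth(truth, 400, seed=3000 + rep)
            r = fit(BLCSSpec(constraints=("gamma1",)), tab,
                    EstimatorOptions(compute_se=False))
            vals.append(r.chisq)
        mean = np.mean(vals)
        assert abs(mean - 1.0) < 3 * math.sqrt(2 * 1 / 60) + 0.2
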