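"""Weighted least squares route: fitting, inference, and the dual-route identity."""

import numpy as np
import pytest

from hkmeta import (
    DegreesOfFreedomError,
    SingularDesignError,
    Tau2Estimate,
    build_design,
    equivalence_report,
    fit_random_effects,
    fit_wls,
    hk_scale_factor,
    metareg_inference,
)

from conftest import random_meta_dataset


class TestFitWls:
    def test_intercept_only_reduces_to_pooling(self):
        y, v, _ = random_meta_dataset(0)
        t2 = Tau2Estimate(0.08, "fixed")
        pooled = fit_random_effects((y, v), t2)
        reg = fit_wls(y, build_design(n=len(y)), 1.0 / (v + t2.tau2))
        assert reg.beta[0] == pytest.approx(pooled.mu_hat, rel=1e-12)
        assert reg.cov_unscaled[0, 0] == pytest.approx(pooled.V, rel=1e-12)
        assert reg.k_hat == pytest.approx(hk_scale_factor(pooled), rel=1e-12)

    def test_perfect_linear_data(self):
        design = build_design(np.array([0.0, 1.0, 2.0]))
        reg = fit_wls(np.array([1.0, 3.0, 5.0]), design, np.array([0.3, 1.0, 2.0]))
        assert reg.beta == pytest.approx([1.0, 2.0], abs=1e-12)
        assert reg.k_hat == pytest.approx(0.0, abs=1e-24)
        assert reg.df == 1

    def test_matches_rescaled_ols_oracle(self):
        # sqrt(w)-rescaled ordinary least squares solves the same normal equations
        y, v, Z = random_meta_dataset(17, n=8, n_cov=2)
        design = build_design(Z)
        w = 1.0 / (v + 0.1)
        reg = fit_wls(y, design, w)
        sw = np.sqrt(w)
        beta_ols, *_ = np.linalg.lstsq(design.X * sw[:, None], y * sw, rcond=None)
        assert reg.beta == pytest.approx(beta_ols, abs=1e-10)

    def test_fitted_plus_residuals(self):
        y, v, Z = random_meta_dataset(4, n_cov=1)
        reg = fit_wls(y, build_design(Z), 1.0 / v)
        assert reg.fitted + reg.residuals == pytest.approx(y, rel=1e-12)

    @pytest.mark.parametrize("c", [0.5, 3.0, 1e5])
    def test_beta_invariant_to_weight_rescaling(self, c):
        y, v, Z = random_meta_dataset(8, n_cov=2)
        base = fit_wls(y, build_design(Z), 1.0 / v)
        scaled = fit_wls(y, build_design(Z), c / v)
        assert scaled.beta == pytest.approx(base.beta, rel=1e-11)
        assert scaled.cov_unscaled == pytest.approx(base.cov_unscaled / c, rel=1e-11)

    def test_rank_deficiency_rejected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(SingularDesignError):
            build_design(np.column_stack([x, 2 * x]))

    def test_too_few_studies_rejected(self):
        with pytest.raises(DegreesOfFreedomError):
            fit_wls(np.zeros(2), build_design(np.array([0.0, 1.0])), np.ones(2))


class TestMetaregInference:
    @pytest.mark.parametrize("seed", range(8))
    def test_se_ratio_is_sqrt_khat(self, seed):
        y, v, Z = random_meta_dataset(seed, n_cov=2)
        reg = fit_wls(y, build_design(Z), 1.0 / (v + 0.05))
        conv = metareg_inference(reg, "conventional")
        hk = metareg_inference(reg, "hk")
        ratio = np.sqrt(reg.k_hat)
        for c, h in zip(conv, hk):
            assert h.estimate == c.estimate
            assert h.se == pytest.approx(c.se * ratio, rel=1e-12)

    def test_hk_uses_t_reference_with_n_minus_p_df(self):
        y, v, Z = random_meta_dataset(1, n=10, n_cov=2)
        reg = fit_wls(y, build_design(Z), 1.0 / v)
        for r in metareg_inference(reg, "hk"):
            assert r.df == 7
        for r in metareg_inference(reg, "conventional"):
            assert r.df is None

    @pytest.mark.parametrize("seed", range(6))
    def test_hk_wider_iff_scale_exceeds_zt_ratio(self, seed):
        from scipy import stats

        y, v, Z = random_meta_dataset(seed, n_cov=1)
        reg = fit_wls(y, build_design(Z), 1.0 / (v + 0.02))
        z = stats.norm.ppf(0.975)
        t = stats.t.ppf(0.975, reg.df)
        wider = np.sqrt(reg.k_hat) > z / t
        for c, h in zip(
            metareg_inference(reg, "conventional"), metareg_inference(reg, "hk")
        ):
            assert (h.width > c.width) == wider


class TestEquivalenceReport:
    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n_cov", [0, 1, 2])
    def test_dual_route_identity(self, seed, n_cov):
        y, v, Z = random_meta_dataset(seed, n_cov=n_cov)
        rep = equivalence_report((y, v), covariates=Z)
        assert rep.passed, rep.discrepancies

    def test_report_records_all_quantities(self):
        y, v, _ = random_meta_dataset(0)
        rep = equivalence_report((y, v))
        assert {
            "estimates",
            "k_hat",
            "se_conventional",
            "se_hk",
            "p_conventional",
            "p_hk",
            "ci_conventional",
            "ci_hk",
        } <= set(rep.discrepancies)
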