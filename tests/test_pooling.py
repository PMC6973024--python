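"""Intercept-only pooling, the two inference methods, and constrained variants."""

import math

import numpy as np
import pytest
from scipy import stats

from hkmeta import (
    InsufficientDataError,
    Tau2Estimate,
    conventional_inference,
    fit_random_effects,
    hk_inference,
    hk_scale_factor,
)

from conftest import random_meta_dataset

FIXED0 = Tau2Estimate(0.0, "fixed")


class TestPooling:
    def test_equal_weights(self):
        fit = fit_random_effects(([0.0, 1.0], [1.0, 1.0]), FIXED0)
        assert fit.mu_hat == pytest.approx(0.5)
        assert fit.V == pytest.approx(0.5)

    def test_unequal_weights_hand_computed(self):
        fit = fit_random_effects(([0.0, 1.0, 2.0], [1.0, 0.5, 2.0]), FIXED0)
        assert fit.weights == pytest.approx([1.0, 2.0, 0.5])
        assert fit.mu_hat == pytest.approx(3.0 / 3.5)
        assert fit.V == pytest.approx(1.0 / 3.5)

    def test_pooled_fit_invariants(self):
        y, v, _ = random_meta_dataset(3)
        fit = fit_random_effects((y, v), Tau2Estimate(0.07, "fixed"))
        assert np.all(fit.weights > 0)
        assert fit.V == pytest.approx(1.0 / fit.weights.sum(), rel=1e-14)
        assert fit.mu_hat == pytest.approx((fit.weights * y).sum() / fit.weights.sum())

    @pytest.mark.parametrize("c", [0.1, 2.0, 1e4])
    def test_weight_rescaling(self, c):
        # scaling all total variances by 1/c scales weights by c: mu unchanged, V by 1/c
        y, v, _ = random_meta_dataset(9)
        base = fit_random_effects((y, v), FIXED0)
        scaled = fit_random_effects((y, v / c), FIXED0)
        assert scaled.mu_hat == pytest.approx(base.mu_hat, rel=1e-12)
        assert scaled.V == pytest.approx(base.V / c, rel=1e-12)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_random_effects(([1.0], [0.5]), FIXED0)


class TestConventionalInference:
    def test_null_estimate(self):
        fit = fit_random_effects(([-1.0, 1.0], [1.0, 1.0]), FIXED0)
        res = conventional_inference(fit)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)
        assert res.ci_lower == pytest.approx(-res.ci_upper)

    def test_normal_quantile_interval(self):
        fit = fit_random_effects(([0.0, 1.0, 2.0], [1.0, 0.5, 2.0]), FIXED0)
        res = conventional_inference(fit, alpha=0.05)
        half = 1.959963984540054 * math.sqrt(1.0 / 3.5)
        assert res.ci_lower == pytest.approx(fit.mu_hat - half, abs=1e-12)
        assert res.ci_upper == pytest.approx(fit.mu_hat + half, abs=1e-12)
        assert res.df is None


class TestHkScaleFactor:
    def test_perfect_homogeneity(self):
        fit = fit_random_effects(([0.7, 0.7, 0.7], [0.2, 0.2, 0.2]), FIXED0)
        assert hk_scale_factor(fit) == 0.0

    def test_hand_computed(self):
        fit = fit_random_effects(([0.0, 1.0], [1.0, 1.0]), FIXED0)
        assert hk_scale_factor(fit) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_higgins_thompson_h2_at_tau_zero(self, seed):
        # with tau2 forced to 0 the scale factor is Q/(n-1) with fixed-effect weights
        y, v, _ = random_meta_dataset(seed)
        fit = fit_random_effects((y, v), FIXED0)
        w = 1.0 / v
        q = float((w * (y - (w * y).sum() / w.sum()) ** 2).sum())
        assert hk_scale_factor(fit) == pytest.approx(q / (len(y) - 1), rel=1e-12)


class TestHkInference:
    @pytest.mark.parametrize("seed", range(6))
    def test_point_estimate_and_vhk_identity(self, seed):
        y, v, _ = random_meta_dataset(seed)
        fit = fit_random_effects((y, v), Tau2Estimate(0.1, "fixed"))
        conv, hk = conventional_inference(fit), hk_inference(fit)
        assert hk.estimate == conv.estimate  # HK never moves the point estimate
        assert hk.se**2 == pytest.approx(hk_scale_factor(fit) * fit.V, rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_equal_variances_reduce_to_one_sample_t(self, seed):
        # equal total variances: pooled mean = arithmetic mean and the HK
        # statistic equals the one-sample t statistic
        rng = np.random.default_rng(seed)
        y = rng.normal(0.2, 0.8, 12)
        fit = fit_random_effects((y, np.full(12, 0.3)), Tau2Estimate(0.2, "fixed"))
        res = hk_inference(fit)
        t_ref = stats.ttest_1samp(y, 0.0)
        assert fit.mu_hat == pytest.approx(y.mean(), rel=1e-12)
        assert res.statistic == pytest.approx(t_ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(t_ref.pvalue, rel=1e-10)

    def test_degenerate_zero_scale_flagged(self):
        fit = fit_random_effects(([0.7, 0.7, 0.7], [0.2, 0.2, 0.2]), FIXED0)
        res = hk_inference(fit)
        assert res.degenerate
        assert res.ci_lower == res.ci_upper == fit.mu_hat
        assert math.isnan(res.statistic)

    def test_two_studies_allowed(self):
        fit = fit_random_effects(([0.0, 1.0], [1.0, 1.0]), FIXED0)
        assert hk_inference(fit).df == 1


class TestConstraints:
    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.1])
    def test_zt_width_is_max_of_both_methods(self, seed, alpha):
        y, v, _ = random_meta_dataset(seed)
        fit = fit_random_effects((y, v), Tau2Estimate(0.05, "fixed"))
        w_conv = conventional_inference(fit, alpha).width
        w_hk = hk_inference(fit, alpha, "none").width
        w_zt = hk_inference(fit, alpha, "zt").width
        assert w_zt == pytest.approx(max(w_conv, w_hk), rel=1e-12)

    def test_small_h2_zt_matches_conventional_width_exactly(self):
        # nearly homogeneous data force H* < z/t so the zt floor binds
        y = np.array([0.5, 0.5001, 0.4999, 0.5])
        fit = fit_random_effects((y, np.full(4, 0.2)), FIXED0)
        z = stats.norm.ppf(0.975)
        t = stats.t.ppf(0.975, 3)
        assert hk_scale_factor(fit) < (z / t) ** 2
        w_conv = conventional_inference(fit).width
        assert hk_inference(fit, 0.05, "zt").width == pytest.approx(w_conv, rel=1e-14)

    @pytest.mark.parametrize("seed", range(10))
    def test_unit_at_least_as_wide_as_zt(self, seed):
        # max(H*2, 1) >= max(H*2, (z/t)^2) because z < t
        y, v, _ = random_meta_dataset(seed)
        fit = fit_random_effects((y, v), Tau2Estimate(0.05, "fixed"))
        assert (
            hk_inference(fit, 0.05, "unit").width
            >= hk_inference(fit, 0.05, "zt").width - 1e-15
        )
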