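"""Heterogeneity statistics, REML, and Knapp-Hartung pooling."""

import numpy as np
import pytest

from rgmeta import (
    cochran_q,
    i_squared,
    pool_random,
    reml_tau2,
    restricted_loglik,
    typical_within_variance,
)
from conftest import grid_golden_reml, make_effects


class TestCochranQ:
    def test_identical_effects_give_zero(self):
        eff = make_effects([0.6, 0.6, 0.6], [0.01, 0.002, 0.05])
        q, df, p = cochran_q(eff)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_studies(self):
        # w = 100 each, weighted mean 0.55: Q = 100*0.05^2 * 2 = 0.5
        q, df, p = cochran_q(make_effects([0.5, 0.6], [0.01, 0.01]))
        assert q == pytest.approx(0.5, rel=1e-12)
        assert df == 1

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            cochran_q(make_effects([0.5], [0.01]))


class TestISquared:
    def test_truncates_at_zero_when_q_below_df(self):
        i2_q, _ = i_squared(3.0, 10, 0.0, 0.01)
        assert i2_q == 0.0

    def test_zero_tau2_gives_zero_i2_tau(self):
        _, i2_tau = i_squared(50.0, 10, 0.0, 0.01)
        assert i2_tau == 0.0

    def test_zero_q_convention(self):
        assert i_squared(0.0, 5, 0.0, 0.01) == (0.0, 0.0)

    def test_q_based_value_at_published_heterogeneity(self):
        """Q = 204.64 on 24 df gives a Q-based I^2 of 88.27%.

        This differs from the tau^2-based index by several points at
        this level of heterogeneity, which is why the package computes
        and reports both flavors.
        """
        i2_q, _ = i_squared(204.64, 24, 0.0, 0.01)
        assert i2_q == pytest.approx(100 * (204.64 - 24) / 204.64, abs=1e-10)
        assert i2_q == pytest.approx(88.27, abs=0.01)

    def test_typical_within_variance_equal_case(self):
        # with equal v the typical variance reduces to v exactly
        assert typical_within_variance([0.02] * 8) == pytest.approx(0.02, rel=1e-12)


class TestREML:
    def test_equal_variance_closed_form(self):
        """Balanced case: tau2_hat = max(0, sample variance of T - v)."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            t = rng.normal(0.6, 0.08, size=12)
            v = 0.002
            eff = make_effects(t, np.full(12, v))
            expected = max(0.0, np.var(t, ddof=1) - v)
            assert reml_tau2(eff) == pytest.approx(expected, abs=1e-8)

    def test_boundary_zero_for_tight_data(self):
        eff = make_effects([0.60, 0.601, 0.599, 0.6005], [0.01] * 4)
        assert reml_tau2(eff) == 0.0

    def test_matches_grid_golden_oracle(self):
        rng = np.random.default_rng(7)
        for k in (5, 10, 25):
            v = rng.uniform(5e-4, 5e-3, size=k)
            t = rng.normal(0.58, 0.06, size=k) + rng.normal(0, np.sqrt(v))
            eff = make_effects(t, v)
            assert reml_tau2(eff) == pytest.approx(grid_golden_reml(eff), abs=1e-6)

    def test_with_design_matrix_matches_oracle(self):
        rng = np.random.default_rng(11)
        k = 15
        v = rng.uniform(5e-4, 5e-3, size=k)
        x = rng.normal(size=k)
        t = 0.58 + 0.03 * x + rng.normal(0, np.sqrt(v + 0.002))
        eff = make_effects(t, v)
        X = np.column_stack([np.ones(k), x])
        assert reml_tau2(eff, design=X) == pytest.approx(grid_golden_reml(eff, design=X), abs=1e-6)

    def test_needs_more_studies_than_columns(self):
        eff = make_effects([0.5], [0.01])
        with pytest.raises(ValueError):
            reml_tau2(eff)

    def test_loglik_is_maximal_at_estimate_and_falls_in_tail(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(1e-3, 5e-3, size=10)
        t = rng.normal(0.6, 0.05, size=10)
        eff = make_effects(t, v)
        tau2 = reml_tau2(eff)
        ll_hat = restricted_loglik(tau2, eff)
        grid = np.linspace(0, 10 * (v.max() + np.var(t, ddof=1)), 500)
        assert ll_hat >= max(restricted_loglik(g, eff) for g in grid) - 1e-6
        assert restricted_loglik(grid[-1], eff) < ll_hat


class TestPoolRandom:
    def test_equal_weights_reduce_to_arithmetic_mean(self):
        t = [0.5, 0.55, 0.62, 0.58]
        res = pool_random(make_effects(t, [0.01] * 4), tau2=0.0)
        assert res.mu_t == pytest.approx(np.mean(t), rel=1e-12)

    def test_zero_tau2_is_fixed_effect_mean(self):
        t = np.array([0.5, 0.6, 0.7])
        v = np.array([0.01, 0.02, 0.005])
        res = pool_random(make_effects(t, v), tau2=0.0)
        assert res.mu_t == pytest.approx(np.sum(t / v) / np.sum(1 / v), rel=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        t = rng.normal(0.6, 0.05, size=8)
        v = rng.uniform(1e-3, 5e-3, size=8)
        r1 = pool_random(make_effects(t, v))
        r2 = pool_random(make_effects(t + 0.1, v))
        assert r2.mu_t - r1.mu_t == pytest.approx(0.1, abs=1e-9)
        assert r2.tau2 == pytest.approx(r1.tau2, abs=1e-10)

    def test_weight_percents_sum_to_100(self, fixture_records):
        from rgmeta import transform_studies

        res = pool_random(transform_studies(fixture_records))
        assert res.weight_percents.sum() == pytest.approx(100.0, abs=0.01)

    def test_interval_degenerates_with_zero_residuals(self):
        res = pool_random(make_effects([0.6] * 5, [0.01, 0.02, 0.03, 0.04, 0.05]), tau2=0.0)
        assert res.se_kh == 0.0
        assert res.ci_t[0] == res.ci_t[1] == res.mu_t

    def test_alpha_scale_endpoints_swap_and_contain(self):
        rng = np.random.default_rng(9)
        t = rng.normal(0.6, 0.05, size=10)
        v = rng.uniform(1e-3, 5e-3, size=10)
        res = pool_random(make_effects(t, v))
        assert res.ci_alpha[0] < res.alpha_pooled < res.ci_alpha[1]
        assert res.ci_alpha[0] == pytest.approx(1 - res.ci_t[1] ** 3)
        assert res.ci_alpha[1] == pytest.approx(1 - res.ci_t[0] ** 3)

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            pool_random(make_effects([0.5], [0.01]))


class TestAgainstMetafor:
    """Frozen cross-check against R metafor 4.8 (rma, method=REML, test=knha).

    Reference values computed once with:
        yi = (0.52, 0.61, 0.48, 0.66, 0.58, 0.70)
        vi = (0.0021, 0.0008, 0.0031, 0.0012, 0.0047, 0.0018)
    """

    yi = [0.52, 0.61, 0.48, 0.66, 0.58, 0.70]
    vi = [0.0021, 0.0008, 0.0031, 0.0012, 0.0047, 0.0018]

    def test_pooled_estimate_interval_and_heterogeneity(self):
        res = pool_random(make_effects(self.yi, self.vi))
        assert res.mu_t == pytest.approx(0.5979294173, abs=5e-8)
        assert res.se_kh == pytest.approx(0.0335457260, abs=5e-8)
        assert res.ci_t[0] == pytest.approx(0.5116973834, abs=5e-8)
        assert res.ci_t[1] == pytest.approx(0.6841614513, abs=5e-8)
        assert res.tau2 == pytest.approx(0.0046134738, abs=5e-8)
        assert res.q_stat == pytest.approx(16.0835123971, abs=1e-9)
        assert res.q_p == pytest.approx(0.0066096431, abs=1e-9)
        assert res.i2_tau == pytest.approx(72.4113689473, abs=5e-4)
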