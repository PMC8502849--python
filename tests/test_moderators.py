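"""Meta-regression, weighted subgroup ANOVA, and the Pearson follow-up."""

import numpy as np
import pytest

from rgmeta import (
    StudyRecord,
    meta_regression,
    pearson_followup,
    run_all_moderators,
    subgroup_anova,
    transform_studies,
)
from conftest import make_effects


def random_effects(rng, k, tau=0.04):
    v = rng.uniform(5e-4, 5e-3, size=k)
    t = rng.normal(0.58, tau, size=k) + rng.normal(0, np.sqrt(v))
    return make_effects(t, v)


class TestMetaRegression:
    def test_knapp_hartung_df_bookkeeping(self):
        rng = np.random.default_rng(0)
        eff = random_effects(rng, 21)
        res = meta_regression(eff, rng.normal(size=21), moderator="age_mean")
        assert res.k_used == 21
        assert res.omnibus_df == (1, 19)
        assert res.qe_df == 19
        # omnibus F equals the squared slope t for a single moderator
        assert res.omnibus_f == pytest.approx(res.coefficients[1].t_stat ** 2, rel=1e-10)

    def test_matches_metafor_mixed_effects_fit(self):
        """Frozen cross-check against R metafor 4.8 (rma mods=~x, knha)."""
        yi = [0.52, 0.61, 0.48, 0.66, 0.58, 0.70]
        vi = [0.0021, 0.0008, 0.0031, 0.0012, 0.0047, 0.0018]
        x = [1.2, 3.4, 0.8, 4.1, 2.0, 5.0]
        res = meta_regression(make_effects(yi, vi), x)
        b0, b1 = res.coefficients
        assert b0.b == pytest.approx(0.4538668344, abs=1e-9)
        assert b1.b == pytest.approx(0.0487580762, abs=1e-9)
        assert b1.se == pytest.approx(0.0039280707, abs=1e-9)
        assert b1.p == pytest.approx(0.0002421702, abs=1e-8)
        assert res.omnibus_f == pytest.approx(154.0758336202, rel=1e-7)
        assert res.qe == pytest.approx(0.4069821940, abs=1e-9)
        assert res.tau2_residual == pytest.approx(0.0, abs=1e-10)
        assert res.r2_percent == pytest.approx(100.0)

    def test_r2_truncation_exercised(self):
        """REML may raise tau^2 when a useless moderator is added; R^2 is
        then truncated at 0 rather than reported negative."""
        rng = np.random.default_rng(18)
        found = False
        for _ in range(40):
            eff = random_effects(rng, 8)
            res = meta_regression(eff, rng.normal(size=8))
            assert res.r2_percent >= 0.0
            if res.tau2_residual > res.tau2_null and res.r2_percent == 0.0:
                found = True
        assert found, "no replicate exercised the truncation branch"

    def test_constant_moderator_rejected(self):
        eff = random_effects(np.random.default_rng(1), 10)
        with pytest.raises(ValueError, match="no variance"):
            meta_regression(eff, np.ones(10))

    def test_small_subset_rejected(self):
        eff = random_effects(np.random.default_rng(2), 2)
        with pytest.raises(ValueError):
            meta_regression(eff, np.array([1.0, 2.0]))

    def test_small_sample_warning(self, caplog):
        rng = np.random.default_rng(3)
        eff = random_effects(rng, 4)
        with caplog.at_level("WARNING", logger="rgmeta"):
            meta_regression(eff, rng.normal(size=4), moderator="score_sd")
        assert any("score_sd" in m and "k=4" in m for m in caplog.messages)


class TestSubgroupAnova:
    def test_two_level_factor_equals_dummy_regression(self):
        rng = np.random.default_rng(6)
        eff = random_effects(rng, 14)
        groups = np.array(["b"] * 8 + ["a"] * 6)
        res_a = subgroup_anova(eff, groups)
        res_r = meta_regression(eff, (groups == "a").astype(float))
        assert res_a.omnibus_f == pytest.approx(res_r.omnibus_f, rel=1e-9)
        assert res_a.omnibus_p == pytest.approx(res_r.omnibus_p, rel=1e-9)
        assert res_a.tau2_residual == pytest.approx(res_r.tau2_residual, abs=1e-10)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(7)
        eff = random_effects(rng, 12)
        groups = np.array(list("aabbccaabbcc"))
        f1 = subgroup_anova(eff, groups).omnibus_f
        relabel = {"a": "z", "b": "m", "c": "a"}
        f2 = subgroup_anova(eff, [relabel[g] for g in groups]).omnibus_f
        assert f2 == pytest.approx(f1, rel=1e-10)

    def test_singleton_level_runs_with_warning(self, caplog):
        rng = np.random.default_rng(8)
        eff = random_effects(rng, 25)
        groups = ["asia"] * 5 + ["europe"] * 17 + ["americas"] + ["oceania"] * 2
        with caplog.at_level("WARNING", logger="rgmeta"):
            res = subgroup_anova(eff, groups, moderator="continent")
        assert res.omnibus_df == (3, 21)
        assert any("americas" in m for m in caplog.messages)
        assert {lm.level: lm.k for lm in res.level_means} == {
            "asia": 5, "europe": 17, "americas": 1, "oceania": 2
        }

    def test_level_means_back_transformed_and_ordered(self):
        rng = np.random.default_rng(9)
        eff = random_effects(rng, 10)
        res = subgroup_anova(eff, ["a"] * 5 + ["b"] * 5)
        for lm in res.level_means:
            assert lm.ci_alpha[0] < lm.alpha < lm.ci_alpha[1]
            assert lm.alpha == pytest.approx(1 - lm.mean_t**3)

    def test_single_group_rejected(self):
        eff = random_effects(np.random.default_rng(10), 5)
        with pytest.raises(ValueError, match="single level"):
            subgroup_anova(eff, ["a"] * 5)


class TestPearsonFollowup:
    def test_perfect_linear_association(self):
        r, p = pearson_followup([0.5, 0.6, 0.7, 0.8], [1.0, 2.0, 3.0, 4.0])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_sign_opposite_to_t_scale_slope(self):
        """For a monotone alpha-moderator relation, the raw-alpha Pearson r
        and the T-scale regression slope have opposite signs."""
        rng = np.random.default_rng(12)
        x = np.sort(rng.uniform(30, 60, size=15))
        alphas = np.clip(0.7 + 0.004 * (x - 45) + rng.normal(0, 0.01, 15), 0.05, 0.95)
        recs = [StudyRecord(f"s{i}", float(a), 200) for i, a in enumerate(alphas)]
        eff = transform_studies(recs)
        slope = meta_regression(eff, x).coefficients[1].b
        r, _ = pearson_followup(alphas, x)
        assert np.sign(r) == -np.sign(slope)
        assert r > 0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_followup([0.5, 0.5, 0.5], [1.0, 2.0, 3.0])


class TestRunAllModerators:
    def test_default_spec_on_fixture(self, fixture_records):
        batch = run_all_moderators(fixture_records)
        kinds = [(r.moderator, r.kind) for r in batch.results]
        assert sum(k == "continuous" for _, k in kinds) == 7
        assert sum(k == "categorical" for _, k in kinds) == 4
        assert batch.skipped == []
        k_used = [r.k_used for r in batch.results if r.kind == "continuous"]
        assert k_used == [25, 22, 22, 21, 17, 5, 4]
        # tau^2 is re-estimated per subset: subsets differ, so must the values
        tau2s = {r.moderator: r.tau2_null for r in batch.results}
        assert tau2s["age_mean"] != tau2s["year"]

    def test_failure_does_not_abort_batch(self, fixture_records):
        # make one moderator constant so its analysis fails
        import dataclasses

        broken = [dataclasses.replace(s, year=2015) for s in fixture_records]
        batch = run_all_moderators(broken)
        assert ("year", ) == tuple(m for m, _ in batch.skipped) or any(
            m == "year" for m, _ in batch.skipped
        )
        assert len(batch.results) == 10

    def test_empty_spec(self, fixture_records):
        batch = run_all_moderators(fixture_records, spec=[])
        assert batch.results == [] and batch.skipped == []
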