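"""Normalization, outcomes and the statistical battery vs references."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from grasplearn import synth
from grasplearn.stats import (BlockSeries, build_report, denormalize_group,
                              intra_training_rate, normalize_subject,
                              one_sample_ttest, oneway_anova,
                              post_training_effect, rm_anova, tukey_posthoc,
                              two_sample_ttest)
from grasplearn.synth import FeedbackMode, LearningParams, generate_study


def _series(pre, training, post):
    return BlockSeries("S01", "IBF", "completion_time",
                       np.asarray(pre, dtype=float),
                       np.asarray(training, dtype=float),
                       np.asarray(post, dtype=float))


class TestNormalization:
    def test_constant_subject_becomes_unity(self):
        s = _series([2.0] * 15, [2.0] * 30, [2.0] * 15)
        n = normalize_subject(s)
        assert np.allclose(n.pre, 1.0)
        assert np.allclose(n.training, 1.0)
        assert np.allclose(n.post, 1.0)

    def test_division_by_pre_mean(self):
        s = _series([2.0] * 15, [1.5] * 30, [1.8] * 15)
        n = normalize_subject(s)
        assert np.allclose(n.training, 0.75)
        assert n.pre.mean() == pytest.approx(1.0, abs=1e-15)

    def test_round_trip_exact(self):
        rng = np.random.default_rng(5)
        s = _series(rng.uniform(1, 2, 15), rng.uniform(1, 2, 30),
                    rng.uniform(1, 2, 15))
        pre_mean = s.pre.mean()
        n = normalize_subject(s)
        assert np.allclose(denormalize_group(n.training, pre_mean),
                           s.training, atol=1e-12, rtol=0)

    def test_group_level_identity(self):
        """De-normalized group pre mean equals the raw group pre mean."""
        rng = np.random.default_rng(8)
        pre_blocks = [rng.uniform(1, 3, 15) for _ in range(6)]
        group_pre = np.mean([b.mean() for b in pre_blocks])
        norm_means = [normalize_subject(
            _series(b, b, b)).pre.mean() for b in pre_blocks]
        # each normalized pre mean is exactly 1
        recovered = np.mean([denormalize_group(m, group_pre)
                             for m in norm_means])
        assert recovered == pytest.approx(group_pre, abs=1e-12)

    def test_denormalize_examples(self):
        assert denormalize_group(1.0, 1.48) == pytest.approx(1.48)
        assert denormalize_group(0.9, 0.25) == pytest.approx(0.225)

    def test_zero_pre_mean_rejected(self):
        with pytest.raises(ValueError):
            normalize_subject(_series([0.0] * 15, [1.0] * 30, [1.0] * 15))


class TestOutcomes:
    def test_constant_block_zero_slope(self):
        assert intra_training_rate([1.5] * 30) == 0.0

    def test_exact_linear_fit(self):
        k = np.arange(1, 31)
        assert intra_training_rate(2.0 - 0.01 * k) == pytest.approx(
            -0.01, abs=1e-14)

    def test_slope_matches_covariance_form(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.normal(size=30)
            k = np.arange(1, 31)
            ref = np.cov(k, y, ddof=1)[0, 1] / np.var(k, ddof=1)
            assert intra_training_rate(y) == pytest.approx(ref, abs=1e-12)

    def test_post_effect_sign_and_invariance(self):
        assert post_training_effect([1.50] * 15, [1.41] * 15) == \
            pytest.approx(-0.09)
        rng = np.random.default_rng(3)
        pre, post = rng.uniform(1, 2, 15), rng.uniform(1, 2, 15)
        a = post_training_effect(pre, post)
        b = post_training_effect(np.sort(pre), post[::-1])
        assert a == pytest.approx(b, abs=1e-15)


class TestRmAnova:
    def test_identical_blocks_give_zero_f(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 3))
        res = rm_anova(X)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_hand_worked_three_by_three(self):
        # partitioned sums of squares computed by hand for this table:
        X = np.array([[4.0, 6.0, 8.0],
                      [5.0, 7.0, 6.0],
                      [3.0, 4.0, 5.0]])
        # grand mean 48/9; SS_level = 3*sum((4,17/3,19/3)-16/3)^2 = 8.667
        # SS_subject = 3*((6-16/3)^2+(6-16/3)^2+(4-16/3)^2) = 8/3+...
        grand = X.mean()
        ss_level = 3 * ((X.mean(axis=0) - grand) ** 2).sum()
        ss_subj = 3 * ((X.mean(axis=1) - grand) ** 2).sum()
        ss_err = ((X - grand) ** 2).sum() - ss_level - ss_subj
        F_hand = (ss_level / 2) / (ss_err / 4)
        res = rm_anova(X)
        assert res.F == pytest.approx(F_hand, abs=1e-10)

    def test_oracle_equivalence_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(17)
        for _ in range(100):
            n, k = int(rng.integers(4, 12)), int(rng.integers(3, 5))
            X = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            res = rm_anova(X)
            df = pd.DataFrame({
                "y": X.ravel(),
                "subj": np.repeat(np.arange(n), k),
                "level": np.tile(np.arange(k), n)})
            tab = AnovaRM(df, "y", "subj", within=["level"]).fit().anova_table
            assert res.F == pytest.approx(float(tab["F Value"].iloc[0]),
                                          abs=1e-8)
            assert res.p == pytest.approx(float(tab["Pr > F"].iloc[0]),
                                          abs=1e-8)

    def test_pairwise_standard_error_form(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        res = rm_anova(X)
        expected_se = np.sqrt(2 * res.ms_error / 10)
        assert np.allclose(res.pairwise["se"], expected_se)


class TestOnewayAnova:
    def test_equal_means_zero_f(self):
        res = oneway_anova([np.array([1.0, 2.0, 3.0]),
                            np.array([1.0, 2.0, 3.0])])
        assert res.F == 0.0

    def test_hand_computed_three_by_five(self):
        groups = [np.array([1.0, 2, 3, 4, 5]), np.array([2.0, 3, 4, 5, 6]),
                  np.array([4.0, 5, 6, 7, 8])]
        grand = np.concatenate(groups).mean()
        ssb = 5 * sum((g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F_hand = (ssb / 2) / (ssw / 12)
        res = oneway_anova(groups)
        assert res.F == pytest.approx(F_hand, abs=1e-10)

    def test_location_invariance(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(size=7) for _ in range(3)]
        a = oneway_anova(groups)
        b = oneway_anova([g + 42.0 for g in groups])
        assert a.F == pytest.approx(b.F, rel=1e-9)

    def test_oracle_equivalence_scipy(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            groups = [rng.normal(loc=rng.normal(), size=rng.integers(4, 12))
                      for _ in range(int(rng.integers(2, 5)))]
            res = oneway_anova(groups)
            F_ref, p_ref = sps.f_oneway(*groups)
            assert res.F == pytest.approx(float(F_ref), abs=1e-8)
            assert res.p == pytest.approx(float(p_ref), abs=1e-8)


class TestTukey:
    def test_identical_groups_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        tk = tukey_posthoc([g, g.copy()])
        assert tk["p_tukey"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_oracle_equivalence_scipy(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            groups = [rng.normal(loc=rng.normal(), size=6) for _ in range(3)]
            tk = tukey_posthoc(groups)
            ref = sps.tukey_hsd(*groups)
            pairs = [(0, 1), (0, 2), (1, 2)]
            for row, (i, j) in zip(tk.itertuples(), pairs):
                assert row.p_tukey == pytest.approx(
                    float(ref.pvalue[i, j]), abs=1e-6)

    def test_bonferroni_identity_and_scaling(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(size=6) for _ in range(3)]
        raw = tukey_posthoc(groups, bonferroni_families=1)
        scaled = tukey_posthoc(groups, bonferroni_families=3)
        assert np.allclose(scaled["p_adjusted"],
                           np.minimum(1.0, raw["p_tukey"] * 3))
        assert np.allclose(raw["p_adjusted"], raw["p_tukey"])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            tukey_posthoc([np.array([1.0, 2.0])])


class TestTtests:
    def test_symmetric_values_zero_t(self):
        res = one_sample_ttest([-2.0, -1.0, 1.0, 2.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        res = one_sample_ttest([1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-12)

    def test_identical_samples_zero_t(self):
        a = np.array([1.0, 2.0, 3.0])
        assert two_sample_ttest(a, a.copy()).t == 0.0

    def test_zero_variance_flagged(self):
        res = one_sample_ttest([1.0, 1.0, 1.0], mu=1.0)
        assert res.flag == "zero variance"

    def test_oracle_equivalence_scipy(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(3, 20)))
            res = one_sample_ttest(x, mu=0.1)
            ref = sps.ttest_1samp(x, 0.1)
            assert res.t == pytest.approx(float(ref.statistic), abs=1e-10)
            assert res.p == pytest.approx(float(ref.pvalue), abs=1e-10)
            a = rng.normal(size=int(rng.integers(3, 15)))
            b = rng.normal(size=int(rng.integers(3, 15)))
            res2 = two_sample_ttest(a, b)
            ref2 = sps.ttest_ind(a, b)
            assert res2.t == pytest.approx(float(ref2.statistic), abs=1e-10)
            assert res2.p == pytest.approx(float(ref2.pvalue), abs=1e-10)


class TestBuildReport:
    def test_zero_noise_slope_recovery(self):
        params = LearningParams.noiseless()
        params.slope[FeedbackMode.IBF]["completion_time"] = -0.005
        study = generate_study(3, params, seed=1)
        rep = build_report(study.to_frame())
        r = rep.outcomes
        ibf = r[(r["mode"] == "IBF") & (r["metric"] == "completion_time")]
        assert np.allclose(ibf["intra_training_rate"], -0.005, atol=1e-6)

    def test_no_effects_no_noise_all_outcomes_zero(self):
        params = LearningParams.noiseless()
        for mode in (FeedbackMode.NF, FeedbackMode.IF, FeedbackMode.IBF):
            for m in synth.METRICS:
                params.slope[mode][m] = 0.0
                params.post_effect[mode][m] = 0.0
        study = generate_study(3, params, seed=2)
        rep = build_report(study.to_frame())
        assert np.allclose(rep.outcomes["intra_training_rate"], 0.0,
                           atol=1e-12)
        assert np.allclose(rep.outcomes["post_training_effect"], 0.0,
                           atol=1e-12)

    def test_injected_signs_recovered_in_report(self):
        study = generate_study(8, seed=77)
        rep = build_report(study.to_frame())
        os = rep.one_sample
        ibf_t = os[(os["mode"] == "IBF")
                   & (os["metric"] == "completion_time")
                   & (os["outcome"] == "intra_training_rate")]
        nf_t = os[(os["mode"] == "NF")
                  & (os["metric"] == "completion_time")
                  & (os["outcome"] == "intra_training_rate")]
        assert float(ibf_t["mean"].iloc[0]) < 0      # improvement
        assert float(nf_t["mean"].iloc[0]) > 0       # fatigue drift

    def test_report_table_shapes(self):
        study = generate_study(4, seed=5)
        rep = build_report(study.to_frame())
        assert len(rep.block_anova) == 9             # 3 metrics x 3 modes
        assert len(rep.block_pairwise) == 27         # ... x 3 block pairs
        assert len(rep.outcome_anova) == 6           # 3 metrics x 2 outcomes
        assert len(rep.one_sample) == 18
        assert set(rep.group_pre_mean) == set(synth.METRICS)
        assert np.all(rep.one_sample["p"].between(0, 1))
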