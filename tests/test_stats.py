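import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom, rankdata

from glymphwave.stats import (
    adjust_covariates,
    classify_stage,
    compare_slopes,
    exact_summary_sample,
    fdr_bh,
    fisher_exact_2x2,
    log_transform_ab42,
    ordinal_trend,
    spearman_assoc,
    two_sample_ttest,
)


class TestClassifyStage:
    @pytest.mark.parametrize(
        "ab42,suvr,expected",
        [
            (250.0, 0.80, "S1"),
            (150.0, 0.80, "S2"),
            (150.0, 0.95, "S3"),
            (250.0, 0.95, "CSFneg_PETpos"),
            (192.0, 0.872, "S1"),  # both cut-offs are strict inequalities
            (191.999, 0.872, "S2"),
            (191.999, 0.8721, "S3"),
        ],
    )
    def test_quadrants_and_boundaries(self, ab42, suvr, expected):
        assert classify_stage(ab42, suvr) == expected

    def test_missing_value_errors(self):
        with pytest.raises(ValueError):
            classify_stage(None, 0.9)

    def test_staging_partitions_cohort(self, cohort_tiny):
        stages = [r.stage for r in cohort_tiny.records]
        assert all(s in ("S1", "S2", "S3", "CSFneg_PETpos") for s in stages)
        assert len(stages) == sum(cohort_tiny.config.stage_counts)


class TestAdjustCovariates:
    def test_pure_age_effect_becomes_constant(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(60, 85, 60)
        sex = rng.choice(["M", "F"], 60)
        values = 2.0 * age
        adj = adjust_covariates(values, age, sex)
        np.testing.assert_allclose(adj, values.mean(), atol=1e-8)

    def test_age_shift_invariance(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(60, 85, 40)
        sex = rng.choice(["M", "F"], 40)
        values = rng.standard_normal(40)
        np.testing.assert_allclose(
            adjust_covariates(values, age, sex),
            adjust_covariates(values, age + 10, sex),
            atol=1e-9,
        )

    def test_independent_values_nearly_unchanged(self):
        rng = np.random.default_rng(2)
        n = 4000
        values = rng.standard_normal(n)
        adj = adjust_covariates(values, rng.uniform(60, 85, n), rng.choice(["M", "F"], n))
        assert np.corrcoef(adj, values)[0, 1] > 0.999

    def test_constant_sex_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="sex"):
            adjust_covariates(rng.standard_normal(10), rng.uniform(60, 85, 10), ["F"] * 10)


class TestSpearman:
    def test_monotone_gives_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        res = spearman_assoc(x, np.exp(x))
        assert res.statistic == pytest.approx(1.0)

    def test_symmetric_parabola_gives_zero(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        res = spearman_assoc(x, x**2)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_rank_formula_with_ties(self):
        x = np.array([3.0, 1.0, 1.0, 4.0, 2.0, 2.0, 5.0])
        y = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 4.0, 4.0])
        res = spearman_assoc(x, y)
        rx, ry = rankdata(x), rankdata(y)  # average ranks
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.statistic == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            spearman_assoc(np.ones(6), np.arange(6.0))


class TestLogAb42:
    @pytest.mark.parametrize("x,expected", [(np.e, 1.0), (1.0, 0.0), (192.0, 5.2575)])
    def test_values(self, x, expected):
        assert log_transform_ab42(x) == pytest.approx(expected, abs=1e-4)

    def test_non_positive_errors(self):
        with pytest.raises(ValueError):
            log_transform_ab42(0.0)


class TestTwoSampleTTest:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        res = two_sample_ttest(a, a.copy())
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_pooled_closed_form(self):
        a = np.array([4.0, 6.0, 8.0])
        b = np.array([1.0, 2.0, 3.0, 6.0])
        res = two_sample_ttest(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.statistic == pytest.approx(t_hand, abs=1e-12)
        assert res.extras["df"] == na + nb - 2

    def test_summary_reconstruction_gives_printed_age_p(self):
        s2 = exact_summary_sample(23, 70.5, 7.3)
        s1 = exact_summary_sample(50, 71.7, 8.0)
        res = two_sample_ttest(s2, s1)
        assert round(res.p, 2) == 0.54

    def test_welch_flag(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal(10), 3 * rng.standard_normal(20)
        assert two_sample_ttest(a, b, equal_var=False).method == "t_welch"

    def test_zero_variance_convention(self):
        res = two_sample_ttest(np.full(3, 2.0), np.full(4, 2.0))
        assert res.p == 1.0


class TestExactSummarySample:
    def test_two_point_closed_form(self):
        vals = np.sort(exact_summary_sample(2, 0.0, 1.0))
        np.testing.assert_allclose(vals, [-np.sqrt(2) / 2, np.sqrt(2) / 2])

    def test_zero_sd(self):
        np.testing.assert_array_equal(exact_summary_sample(5, 10.0, 0.0), np.full(5, 10.0))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        n=st.integers(2, 40),
        mean=st.floats(-50, 50, allow_nan=False),
        sd=st.floats(0.01, 20, allow_nan=False),
    )
    def test_round_trip(self, n, mean, sd):
        vals = exact_summary_sample(n, mean, sd)
        assert vals.mean() == pytest.approx(mean, abs=1e-8 * max(1, abs(mean)))
        assert vals.std(ddof=1) == pytest.approx(sd, rel=1e-8)

    def test_n1_with_sd_errors(self):
        with pytest.raises(ValueError):
            exact_summary_sample(1, 0.0, 1.0)


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by explicit enumeration of the conditional tables."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, total = a + b, a + c, a + b + c + d
    rv = hypergeom(total, col1, row1)
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    p_obs = rv.pmf(a)
    return sum(rv.pmf(k) for k in range(lo, hi + 1) if rv.pmf(k) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_printed_gender_table(self):
        res = fisher_exact_2x2([[22, 28], [16, 7]])
        assert abs(res.p - 0.049) <= 0.001

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p == pytest.approx(1.0)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]).p == 1.0

    def test_matches_enumeration_on_small_tables(self):
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    for d in range(4):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        table = [[a, b], [c, d]]
                        assert fisher_exact_2x2(table).p == pytest.approx(
                            fisher_enumeration_oracle(table), abs=1e-9
                        ), table


class TestOrdinalTrend:
    def test_strong_trend_detected(self):
        rng = np.random.default_rng(5)
        labels = ["S1"] * 50 + ["S2"] * 23 + ["S3"] * 71
        values = np.concatenate(
            [rng.normal(0, 1, 50), rng.normal(1, 1, 23), rng.normal(2, 1, 71)]
        )
        res = ordinal_trend(values, labels)
        assert res.p < 1e-6
        assert res.extras["slope"] > 0

    def test_reverse_parameterization(self):
        rng = np.random.default_rng(6)
        labels = ["S1"] * 30 + ["S2"] * 30 + ["S3"] * 30
        values = np.concatenate([rng.normal(i, 1, 30) for i in range(3)])
        res = ordinal_trend(values, labels, reverse=True)
        assert res.method == "trend_ols_reverse"
        assert res.p < 1e-6

    def test_separation_falls_back_to_penalized(self):
        labels = ["S1"] * 10 + ["S2"] * 10 + ["S3"] * 10
        values = np.concatenate([np.arange(10), 20 + np.arange(10), 40 + np.arange(10.0)])
        with pytest.warns(UserWarning, match="separation"):
            res = ordinal_trend(values, labels)
        assert res.method == "ordinal_proportional_odds_penalized"
        assert np.isfinite(res.p)
        assert res.p < 0.05

    def test_two_stage_minimum(self):
        with pytest.raises(ValueError):
            ordinal_trend(np.arange(5.0), ["S1"] * 5)


class TestFdrBH:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_q_at_least_p_and_bounded(self, pvals):
        q = fdr_bh(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=20)
        q = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCompareSlopes:
    def test_identical_conditions_p_near_one(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(30)
        y = 2 * x + rng.standard_normal(30)
        res = compare_slopes(x, y, y.copy())
        assert res.p > 0.99

    def test_swap_symmetry(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(25)
        yb = 1.5 * x + 0.3 * rng.standard_normal(25)
        ya = 0.2 * x + 0.3 * rng.standard_normal(25)
        assert compare_slopes(x, yb, ya).p == pytest.approx(compare_slopes(x, ya, yb).p)

    def test_detects_slope_change(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(25)
        yb = 2.0 * x + 0.2 * rng.standard_normal(25)
        ya = 0.2 * rng.standard_normal(25)
        res = compare_slopes(x, yb, ya)
        assert res.p < 0.001
        assert abs(res.extras["slope_after"]) < abs(res.extras["slope_before"])

    def test_too_few_subjects_errors(self):
        with pytest.raises(ValueError):
            compare_slopes(np.arange(3.0), np.arange(3.0), np.arange(3.0))
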