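import itertools
import math

import numpy as np
import pytest
from scipy import stats

from warfarin_pgx.evaluation import (
    classification_table,
    classify_dose,
    event_rate,
    group_dose_comparison,
    mean_absolute_error,
    number_needed_to_genotype,
    pearson_chi_square,
    regress_wsd_on_prediction,
)


class TestClassifyDose:
    @pytest.mark.parametrize("predicted,actual,expected", [
        (44.5, 40, "ideal"),            # 11.3% deviation
        (48.1, 40, "overestimation"),   # 20.25% >= 20%
        (48.0, 40, "overestimation"),   # boundary goes to over ("at least 20%")
        (32.0, 40, "underestimation"),
        (40.0, 40, "ideal"),
    ])
    def test_examples(self, predicted, actual, expected):
        assert classify_dose(predicted, actual) == expected

    def test_nonpositive_actual_raises(self):
        with pytest.raises(ValueError):
            classify_dose(40, 0)


class TestMae:
    def test_equal_absolute_errors(self):
        s = mean_absolute_error([40, 50], [45, 45])
        assert s.mae == 5.0 and s.mae_se == 0.0

    def test_unequal_errors(self):
        s = mean_absolute_error([40, 55], [45, 45])
        assert s.mae == pytest.approx(7.5)
        assert s.mae_se == pytest.approx(2.5)  # sd(5,10)/sqrt(2) = sqrt(12.5)/sqrt(2)

    def test_perfect_predictions(self):
        s = mean_absolute_error([40, 45, 50], [40, 45, 50])
        assert s.mae == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mean_absolute_error([1, 2], [1])


class TestRegression:
    def test_exact_proportionality(self):
        res = regress_wsd_on_prediction([10, 20, 30, 40], [20, 40, 60, 80])
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols(self):
        res = regress_wsd_on_prediction([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)
        assert res.r_squared == pytest.approx(0.64)
        assert res.r_squared == pytest.approx(res.r ** 2, abs=1e-9)

    def test_f_equals_t_squared_with_scipy(self):
        rng = np.random.default_rng(11)
        x = rng.normal(40, 10, 30)
        y = 0.8 * x + rng.normal(0, 5, 30)
        res = regress_wsd_on_prediction(x, y)
        fit = stats.linregress(x, y)
        assert res.p_value == pytest.approx(fit.pvalue, rel=1e-9)
        assert res.f_statistic == pytest.approx((fit.slope / fit.stderr) ** 2, rel=1e-9)

    def test_uncorrelated_pairs_have_near_zero_r_squared(self):
        rng = np.random.default_rng(7)
        res = regress_wsd_on_prediction(rng.normal(40, 10, 4000), rng.normal(40, 10, 4000))
        assert res.r_squared < 0.01

    def test_constant_predictor_is_degenerate(self):
        res = regress_wsd_on_prediction([35, 35, 35], [30, 40, 50])
        assert res.degenerate


class TestClassificationTable:
    def test_study_pgx_row_ideal_fraction(self):
        # reconstruct the PGx row from synthetic pairs: 32 ideal, 12 under, 3 over
        actual = [40.0] * 47
        preds = [40.0] * 32 + [28.0] * 12 + [55.0] * 3
        table = classification_table(preds, actual, model="pgx")
        assert (table.ideal, table.underestimation, table.overestimation) == (32, 12, 3)
        assert table.ideal / table.total == pytest.approx(0.681, abs=5e-4)

    def test_all_perfect(self):
        table = classification_table([40] * 5, [40] * 5)
        assert (table.ideal, table.underestimation, table.overestimation) == (5, 0, 0)

    def test_uniform_overestimation(self):
        actual = np.array([30.0, 40.0, 50.0])
        table = classification_table(1.5 * actual, actual)
        assert (table.ideal, table.underestimation, table.overestimation) == (0, 0, 3)

    def test_counts_are_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(3)
        actual = rng.uniform(20, 70, 100)
        preds = rng.uniform(20, 70, 100)
        table = classification_table(preds, actual)
        assert table.total == 100


class TestEventRateAndNng:
    @pytest.mark.parametrize("counts,expected", [
        ((32, 12, 3), 15 / 47),
        ((25, 12, 10), 22 / 47),
        ((21, 15, 11), 26 / 47),
        ((10, 0, 0), 0.0),
    ])
    def test_event_rate(self, counts, expected):
        from warfarin_pgx.evaluation import ClassificationTable

        assert event_rate(ClassificationTable("m", *counts)) == pytest.approx(expected)

    def test_nng_pgx_vs_clinical(self):
        res = number_needed_to_genotype(15 / 47, 22 / 47)
        assert res.arr == pytest.approx(7 / 47)
        assert res.nng == pytest.approx(47 / 7)
        assert round(res.nng, 1) == 6.7

    def test_nng_pgx_vs_fixed(self):
        res = number_needed_to_genotype(15 / 47, 26 / 47)
        assert round(res.nng, 1) == 4.3

    def test_equal_rates_flagged_infinite(self):
        res = number_needed_to_genotype(0.5, 0.5)
        assert res.undefined and math.isinf(res.nng)

    def test_out_of_range_rate_raises(self):
        with pytest.raises(ValueError):
            number_needed_to_genotype(1.2, 0.5)

    def test_nng_at_least_one(self):
        for a, b in [(0.1, 0.9), (0.0, 1.0), (0.3, 0.31)]:
            res = number_needed_to_genotype(a, b)
            assert res.nng >= 1.0


class TestChiSquare:
    def test_study_bleeding_table(self):
        stat, df, p = pearson_chi_square([[19, 25, 11], [23, 19, 2]])
        assert stat == pytest.approx(6.285, abs=1e-3)
        assert df == 2
        assert p == pytest.approx(0.043, abs=1e-3)

    def test_proportional_rows_give_zero(self):
        stat, _, p = pearson_chi_square([[10, 20, 30], [5, 10, 15]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_association_2x2(self):
        stat, df, _ = pearson_chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            pearson_chi_square([[0, 5], [0, 10]])

    def test_matches_brute_force_on_small_2x2_tables(self):
        # independent oracle: explicit O/E sum over all 2x2 tables with both
        # margins positive and every cell <= 6 (margin totals <= 12)
        def oracle(a, b, c, d):
            n = a + b + c + d
            e = [[(a + b) * (a + c) / n, (a + b) * (b + d) / n],
                 [(c + d) * (a + c) / n, (c + d) * (b + d) / n]]
            o = [[a, b], [c, d]]
            return sum((o[i][j] - e[i][j]) ** 2 / e[i][j]
                       for i in range(2) for j in range(2))

        for a, b, c, d in itertools.product(range(7), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            stat, df, p = pearson_chi_square([[a, b], [c, d]])
            assert stat == pytest.approx(oracle(a, b, c, d), abs=1e-10)
            assert df == 1


class TestGroupComparison:
    def test_identical_groups(self):
        t, p = group_dose_comparison([[40, 45, 50], [40, 45, 50]])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_study_vkorc1_anova_from_summaries(self):
        f, p = group_dose_comparison(
            [(15, 51.2, 15.9), (23, 39.1, 13.0), (9, 32.5, 8.8)], from_summaries=True)
        assert f == pytest.approx(6.34, abs=0.01)
        assert p == pytest.approx(0.004, abs=5e-4)

    def test_study_cyp2c9_t_test_from_summaries(self):
        t, p = group_dose_comparison([(34, 42.6, 13.8), (13, 39.4, 17.5)],
                                     from_summaries=True)
        assert t == pytest.approx(0.66, abs=0.01)
        assert 0.51 <= p <= 0.52

    def test_summary_path_matches_raw_path(self):
        rng = np.random.default_rng(2)
        g1, g2, g3 = (rng.normal(m, 10, n) for m, n in ((50, 15), (40, 23), (33, 9)))
        f_raw, p_raw = group_dose_comparison([g1, g2, g3])
        summaries = [(len(g), float(g.mean()), float(g.std(ddof=1))) for g in (g1, g2, g3)]
        f_sum, p_sum = group_dose_comparison(summaries, from_summaries=True)
        assert f_sum == pytest.approx(f_raw, rel=1e-9)
        assert p_sum == pytest.approx(p_raw, rel=1e-9)
        # and the raw path agrees with scipy's one-way ANOVA
        f_scipy, p_scipy = stats.f_oneway(g1, g2, g3)
        assert f_raw == pytest.approx(float(f_scipy), rel=1e-9)

    def test_two_group_raw_matches_scipy_pooled_t(self):
        rng = np.random.default_rng(4)
        g1, g2 = rng.normal(42, 14, 34), rng.normal(39, 17, 13)
        t_ours, p_ours = group_dose_comparison([g1, g2])
        t_scipy, p_scipy = stats.ttest_ind(g1, g2)
        assert t_ours == pytest.approx(float(t_scipy), rel=1e-9)
        assert p_ours == pytest.approx(float(p_scipy), rel=1e-9)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            group_dose_comparison([[1, 2, 3]])
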