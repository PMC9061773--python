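"""Population statistics: pooled t-test, correlation, SEM, boxplots, tables."""

import numpy as np
import pytest
from scipy import stats as sps

from stressfiber.stats_timecourse import (
    PopulationSample,
    assemble_timecourse,
    boxplot_stats,
    pearson_correlation,
    summarize_population,
    two_sample_ttest,
)


class TestTTest:
    def test_identical_samples_do_not_reject(self):
        a = PopulationSample("a", [1.0, 2.0, 3.0, 2.5])
        res = two_sample_ttest(a, PopulationSample("b", a.values))
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert not res.reject_at_alpha

    def test_hand_computed_example(self):
        # means 2 and 5, both variances 1, pooled sp2 = 1, se = sqrt(2/3)
        res = two_sample_ttest(PopulationSample("a", [1, 2, 3]),
                               PopulationSample("b", [4, 5, 6]))
        assert res.df == 4
        assert res.t_stat == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert res.t_stat == pytest.approx(-3.6742, abs=1e-4)
        assert res.p_value == pytest.approx(0.0213, abs=1e-4)
        assert res.reject_at_alpha

    def test_agrees_with_independent_reference(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            x = rng.normal(0, 1, rng.integers(3, 30))
            y = rng.normal(0.3, 1.4, rng.integers(3, 30))
            mine = two_sample_ttest(PopulationSample("x", x),
                                    PopulationSample("y", y))
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert mine.t_stat == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_symmetric_in_sample_order(self):
        a = PopulationSample("a", [1.0, 2.0, 4.0])
        b = PopulationSample("b", [2.0, 5.0, 6.0, 8.0])
        r1 = two_sample_ttest(a, b)
        r2 = two_sample_ttest(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r1.t_stat == pytest.approx(-r2.t_stat, rel=1e-12)

    def test_affine_invariance_up_to_sign(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = rng.normal(1.0, 2.0, size=15)
        base = two_sample_ttest(PopulationSample("x", x),
                                PopulationSample("y", y))
        for a_coef, b_coef in ((2.5, 1.0), (-3.0, 0.5)):
            res = two_sample_ttest(
                PopulationSample("x", a_coef * x + b_coef),
                PopulationSample("y", a_coef * y + b_coef))
            assert abs(res.t_stat) == pytest.approx(abs(base.t_stat), rel=1e-10)
            assert res.p_value == pytest.approx(base.p_value, rel=1e-10)

    def test_zero_pooled_variance_is_an_error(self):
        with pytest.raises(ValueError):
            two_sample_ttest(PopulationSample("a", [1.0, 1.0]),
                             PopulationSample("b", [2.0, 2.0]))

    def test_power_increases_with_effect_size(self):
        rng = np.random.default_rng(123)
        power = {}
        for d in (0.5, 1.0):
            rejections = 0
            for _ in range(400):
                x = rng.normal(0, 1, 20)
                y = rng.normal(d, 1, 20)
                rejections += two_sample_ttest(
                    PopulationSample("x", x),
                    PopulationSample("y", y)).reject_at_alpha
            power[d] = rejections / 400
        assert power[1.0] > power[0.5]


class TestCorrelation:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # sums: cov*n = 5.5, var_x*n = 5, var_y*n = 8.75
        r = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 5])
        assert r == pytest.approx(5.5 / np.sqrt(5 * 8.75), abs=1e-12)
        assert r == pytest.approx(0.8316, abs=5e-4)

    def test_constant_input_is_an_error(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestSummaries:
    def test_constant_sample(self):
        mean, sem = summarize_population(PopulationSample("a", [2, 2, 2]))
        assert mean == 2.0 and sem == 0.0

    def test_closed_form_sem(self):
        mean, sem = summarize_population(PopulationSample("a", [1, 2, 3]))
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(1.0 / np.sqrt(3), abs=1e-4)
        assert sem == pytest.approx(0.5774, abs=1e-4)

    def test_duplication_scaling_follows_sample_sd_arithmetic(self):
        vals = [1.0, 2.0, 3.0]
        n = len(vals)
        mean1, sem1 = summarize_population(PopulationSample("a", vals))
        mean2, sem2 = summarize_population(PopulationSample("a", vals * 2))
        assert mean2 == mean1
        # duplicating: sd'^2 = 2(n-1)/(2n-1) s^2, sem' = sd'/sqrt(2n)
        expected = sem1 * np.sqrt((n - 1) / (2 * n - 1))
        assert sem2 == pytest.approx(expected, rel=1e-12)

    def test_single_value_sem_flagged_undefined(self):
        _, sem = summarize_population(PopulationSample("a", [4.2]))
        assert np.isnan(sem)


class TestBoxplot:
    def test_interpolated_quartiles_one_to_seven(self):
        st = boxplot_stats(PopulationSample("a", np.arange(1.0, 8.0)))
        assert st.median == 4.0
        assert st.q25 == pytest.approx(2.5)
        assert st.q75 == pytest.approx(5.5)
        assert st.outliers.size == 0
        assert st.whisker_low == 1.0 and st.whisker_high == 7.0

    def test_constant_sample_collapses(self):
        st = boxplot_stats(PopulationSample("a", [3.0, 3.0, 3.0]))
        assert st.median == st.q25 == st.q75 == 3.0
        assert st.outliers.size == 0

    def test_extreme_point_is_flagged(self):
        st = boxplot_stats(PopulationSample("a", [1.0, 2.0, 3.0, 100.0]))
        assert list(st.outliers) == [100.0]
        assert st.whisker_high == 3.0

    def test_matches_sort_based_oracle_on_random_samples(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            v = rng.normal(0, rng.uniform(0.5, 3.0), rng.integers(1, 40))
            st = boxplot_stats(PopulationSample("a", v))
            sv = np.sort(v)
            # type-7 quantile oracle by direct order-statistic interpolation
            def q(p):
                hpos = (sv.size - 1) * p
                lo = int(np.floor(hpos))
                hi = min(lo + 1, sv.size - 1)
                return sv[lo] + (hpos - lo) * (sv[hi] - sv[lo])
            assert st.q25 == pytest.approx(q(0.25), rel=1e-12, abs=1e-12)
            assert st.median == pytest.approx(q(0.5), rel=1e-12, abs=1e-12)
            assert st.q75 == pytest.approx(q(0.75), rel=1e-12, abs=1e-12)
            iqr = st.q75 - st.q25
            inside = sv[(sv >= st.q25 - 1.5 * iqr) & (sv <= st.q75 + 1.5 * iqr)]
            assert st.whisker_low == inside.min()
            assert st.whisker_high == inside.max()


class TestTimecourse:
    def test_single_sample_single_row(self):
        table = assemble_timecourse([PopulationSample("0", [0.2, 0.3])])
        assert len(table) == 1
        assert table.loc[0, "time_h"] == 0.0
        assert table.loc[0, "n"] == 2

    def test_rows_sorted_and_means_preserved(self):
        samples = [PopulationSample(str(t), np.full(3, 0.1 * t))
                   for t in (4, 0, 2)]
        table = assemble_timecourse(samples)
        assert list(table["time_h"]) == [0.0, 2.0, 4.0]
        assert list(table["mean_oop"]) == pytest.approx([0.0, 0.2, 0.4])

    def test_control_condition_adds_per_time_tests(self):
        rng = np.random.default_rng(8)
        treated = [PopulationSample(str(t), rng.normal(0.3, 0.05, 10))
                   for t in (0, 14)]
        control = [PopulationSample(str(t), rng.normal(0.8, 0.05, 10))
                   for t in (0, 14)]
        table = assemble_timecourse(treated, control=control)
        assert {"t_stat", "p_value", "reject"} <= set(table.columns)
        assert table["reject"].all()

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assemble_timecourse([PopulationSample("1", [0.1]),
                                 PopulationSample("1.0", [0.2])])

    def test_non_numeric_label_rejected(self):
        with pytest.raises(ValueError, match="not numeric"):
            assemble_timecourse([PopulationSample("early", [0.1])])
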