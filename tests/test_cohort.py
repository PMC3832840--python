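"""Age groups, adjacent-group t-tests, quadratic trajectory fits."""

import numpy as np
import pytest

import adchist as a
from adchist.cohort import (SubjectResult, assign_age_group,
                            compare_adjacent_groups, fit_polynomial,
                            fit_quadratic, group_summary, slope_at_age)


def make_results(ages, values, sexes=None, prefix="s"):
    sexes = sexes or ["female"] * len(ages)
    return [
        SubjectResult(f"{prefix}{i}", float(x), sex, float(y))
        for i, (x, y, sex) in enumerate(zip(ages, values, sexes))
    ]


class TestAgeGroups:
    @pytest.mark.parametrize(
        "age, group",
        [(0.0, 1), (19.99, 1), (20.0, 2), (39.9, 2), (40.0, 3),
         (60.0, 4), (89.9, 4), (90.0, 4)],
    )
    def test_boundary_assignment(self, age, group):
        assert assign_age_group(age) == group

    @pytest.mark.parametrize("age", [-0.1, 90.1])
    def test_out_of_range_rejected(self, age):
        with pytest.raises(ValueError):
            assign_age_group(age)

    def test_single_subject_per_group(self):
        results = make_results([10, 30, 50, 70], [84, 80, 76, 70])
        summaries = group_summary(results)
        assert [s.n for s in summaries] == [1, 1, 1, 1]
        assert [s.mean for s in summaries] == [84, 80, 76, 70]
        assert all(np.isnan(s.sd) for s in summaries)

    def test_hand_computed_mean_and_sd(self):
        results = make_results([25, 35], [80, 82])
        g2 = group_summary(results)[1]
        assert g2.mean == pytest.approx(81.0)
        assert g2.sd == pytest.approx(np.sqrt(2.0))
        assert group_summary(results)[0].n == 0

    def test_simulated_decline_gives_decreasing_group_means(self):
        rng = np.random.default_rng(13)
        ages = rng.uniform(2, 88, 200)
        traj = a.AgeTrajectory(83.5, -0.068, -0.0027, 1.0)
        values = np.clip(traj(ages) + rng.normal(0, 1.0, 200), 1, 99)
        means = [s.mean for s in group_summary(make_results(ages, values))]
        assert means[0] > means[1] > means[2] > means[3]


class TestGroupComparisons:
    def test_identical_groups_give_t0_p1(self):
        ages = [10, 12, 30, 32, 50, 52, 70, 72]
        results = make_results(ages, [80.0] * 8)
        for comp in compare_adjacent_groups(results):
            assert comp.t_statistic == 0.0
            assert comp.p_raw == 1.0
            assert comp.p_corrected == 1.0

    def test_extreme_separation_is_significant_after_correction(self):
        rng = np.random.default_rng(1)
        ages = [10, 12, 14, 16, 30, 32, 34, 36, 50, 52, 54, 56, 70, 72, 74, 76]
        values = np.repeat([20.0, 20.0, 20.0, 10.0], 4) + rng.normal(
            0, 1e-3, 16
        )
        comps = compare_adjacent_groups(make_results(ages, values))
        assert comps[2].p_corrected < 1e-6

    def test_pooled_variance_t_matches_textbook_formula(self):
        results = make_results(
            [5, 6, 25, 30, 35, 45, 50, 55, 70, 71],
            [85, 86, 80, 81, 82, 76, 77, 78, 70, 71],
        )
        comp = compare_adjacent_groups(results)[1]  # group 3 vs group 2
        # pooled variance: s2 = (2*1 + 2*1)/4 = 1; t = -4 / sqrt(2/3)
        expected = -4.0 / np.sqrt(2.0 / 3.0)
        assert comp.t_statistic == pytest.approx(expected, rel=1e-12)
        assert comp.p_corrected == pytest.approx(
            min(1.0, 3 * comp.p_raw)
        )

    def test_degenerate_group_rejected(self):
        results = make_results([10, 30, 32, 50, 52, 70, 72], [80] * 7)
        with pytest.raises(ValueError):
            compare_adjacent_groups(results)

    def test_bonferroni_never_reduces_p(self):
        rng = np.random.default_rng(4)
        ages = np.r_[rng.uniform(0, 20, 5), rng.uniform(20, 40, 5),
                     rng.uniform(40, 60, 5), rng.uniform(60, 90, 5)]
        values = rng.uniform(60, 90, 20)
        for comp in compare_adjacent_groups(make_results(ages, values)):
            assert comp.p_corrected >= comp.p_raw
            assert comp.p_corrected == pytest.approx(min(1.0, 3 * comp.p_raw))


class TestQuadraticFit:
    def test_exact_interpolation_of_three_points(self):
        ages = np.array([10.0, 40.0, 70.0])
        values = 84.2 - 0.105 * ages - 0.0020 * ages**2
        fit = fit_polynomial(ages, values)
        assert fit.c0 == pytest.approx(84.2, abs=1e-9)
        assert fit.c1 == pytest.approx(-0.105, abs=1e-9)
        assert fit.c2 == pytest.approx(-0.0020, abs=1e-9)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_constant_data_gives_flat_fit(self):
        ages = np.linspace(5, 85, 30)
        fit = fit_polynomial(ages, np.full(30, 50.0))
        assert (fit.c0, fit.c1, fit.c2) == pytest.approx((50.0, 0.0, 0.0),
                                                         abs=1e-9)

    def test_matches_closed_form_normal_equations(self):
        """OLS solution vs explicit (X'X)^{-1} X'y on noisy data."""
        rng = np.random.default_rng(8)
        ages = rng.uniform(5, 85, 200)
        values = 83.5 - 0.068 * ages - 0.0027 * ages**2 + rng.normal(
            0, 1.5, 200
        )
        fit = fit_polynomial(ages, values)
        X = np.vander(ages, 3, increasing=True)
        oracle = np.linalg.solve(X.T @ X, X.T @ values)
        got = np.array([fit.c0, fit.c1, fit.c2])
        assert np.max(np.abs(got - oracle) / np.abs(oracle)) <= 1e-9

    def test_recovers_generator_within_sampling_error(self):
        rng = np.random.default_rng(12)
        n = 200
        ages = rng.uniform(5, 85, n)
        truth = (83.5, -0.068, -0.0027)
        values = (truth[0] + truth[1] * ages + truth[2] * ages**2
                  + rng.normal(0, 1.5, n))
        fit = fit_polynomial(ages, values)
        X = np.vander(ages, 3, increasing=True)
        cov = 1.5**2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        got = np.array([fit.c0, fit.c1, fit.c2])
        assert np.all(np.abs(got - truth) < 3 * se)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            fit_polynomial(np.array([10.0, 10.0, 40.0, 40.0]),
                           np.array([1.0, 2.0, 3.0, 4.0]))

    def test_stratified_fit_selects_one_sex(self):
        ages = [10, 20, 30, 40, 50, 60]
        sexes = ["female", "male"] * 3
        values = [80, 70, 78, 68, 76, 66]
        fit_f = fit_quadratic(make_results(ages, values, sexes), "female")
        assert fit_f.n == 3
        assert fit_f.predict(10) == pytest.approx(80.0, abs=1e-8)
        with pytest.raises(ValueError):
            fit_quadratic(make_results(ages, values, sexes), "everyone")


class TestSlope:
    def test_printed_trajectory_slope_at_50(self):
        fit = a.QuadraticFit(83.5, -0.068, -0.0027, 0.0, 319)
        assert slope_at_age(fit, 50.0) == pytest.approx(-0.338)

    def test_zero_curvature_gives_constant_slope(self):
        fit = a.QuadraticFit(80.0, 0.0, 0.0, 0.0, 10)
        assert slope_at_age(fit, 33.0) == 0.0

    def test_slope_is_linear_in_age_and_c1_at_zero(self):
        fit = a.QuadraticFit(83.5, -0.071, -0.0029, 0.0, 162)
        assert slope_at_age(fit, 0.0) == fit.c1
        assert slope_at_age(fit, 80.0) == pytest.approx(-0.071 - 0.464)
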