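"""LOOCV-ROC cutoffs, Kaplan-Meier, permutation log-rank and Cox statistics."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from hepwx.survival_analysis import (
    cox_univariate_log2,
    hazard_percent_change,
    kaplan_meier,
    logrank_permutation_p,
    logrank_statistic,
    loocv_cutoff_and_groups,
    one_year_labels,
    roc_cutoff,
)


class TestOneYearLabels:
    def test_death_before_horizon_is_non_survivor(self):
        labels, inc = one_year_labels([11.42, 12.0, 30.0], [1, 1, 0])
        assert inc.all()
        np.testing.assert_array_equal(labels, [0, 1, 1])

    def test_boundary_convention_at_exactly_twelve_months(self):
        labels, _ = one_year_labels([12.0], [1])
        assert labels[0] == 1

    def test_early_censoring_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="censored before"):
            labels, inc = one_year_labels([6.0, 15.0], [0, 1])
        np.testing.assert_array_equal(inc, [False, True])
        np.testing.assert_array_equal(labels, [1])

    def test_everything_excluded_is_an_error(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="all patients excluded"):
                one_year_labels([3.0, 5.0], [0, 0])


def brute_force_cutoff(values, labels):
    """Enumeration oracle: scan every midpoint threshold, both orientations."""
    v = np.asarray(values, float)
    y = np.asarray(labels, int)
    uniq = np.unique(v)
    best = None
    for thr in 0.5 * (uniq[:-1] + uniq[1:]):
        for orient in ("ge", "le"):
            pred = v >= thr if orient == "ge" else v <= thr
            sens = np.sum(pred & (y == 1)) / y.sum()
            spec = np.sum(~pred & (y == 0)) / (y.size - y.sum())
            d = (1 - sens) ** 2 + (1 - spec) ** 2
            if best is None or d < best[0] - 1e-12:
                best = (d, thr, orient)
    return best


class TestRocCutoff:
    def test_separable_classes_yield_gap_midpoint(self):
        v = np.array([1, 2, 3, 10, 11, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        thr, orient, sens, spec = roc_cutoff(v, y)
        assert 3 < thr < 10 and thr == pytest.approx(6.5)
        assert orient == "ge" and sens == 1.0 and spec == 1.0

    def test_uninformative_values_handled_without_crash(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        while len(set(y)) < 2:
            y = rng.integers(0, 2, 40)
        thr, orient, sens, spec = roc_cutoff(v, y)
        d = (1 - sens) ** 2 + (1 - spec) ** 2
        assert 0.0 <= d <= 0.5  # never worse than the chance diagonal

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle_on_random_small_cases(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 14)
        v = np.round(rng.normal(size=n), 2)
        y = rng.integers(0, 2, n)
        if len(set(y)) < 2 or np.unique(v).size < 2:
            pytest.skip("degenerate draw")
        d_oracle, _, _ = brute_force_cutoff(v, y)
        thr, orient, sens, spec = roc_cutoff(v, y)
        d_mine = (1 - sens) ** 2 + (1 - spec) ** 2
        assert d_mine == pytest.approx(d_oracle, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_cutoff([1.0, 2.0], [1, 1])

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            roc_cutoff([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])


class TestLoocv:
    def test_separable_cohort_reproduces_labels_exactly(self):
        v = np.array([1, 2, 3, 10, 11, 12.0])
        os_m = np.array([4, 5, 6, 20, 25, 30.0])
        ev = np.ones(6, int)
        res = loocv_cutoff_and_groups(v, os_m, ev, n_perm=100, seed=0)
        assert 3 < res.optimal_cutoff < 10
        np.testing.assert_array_equal(
            res.risk_group, ["high"] * 3 + ["low"] * 3)
        assert all(3 < c < 10 for c in res.cutoff_frequency_table)

    def test_constant_values_degenerate_single_group(self):
        v = np.full(6, 2.0)
        os_m = np.array([4, 5, 6, 20, 25, 30.0])
        res = loocv_cutoff_and_groups(v, os_m, np.ones(6, int), n_perm=100)
        assert res.degenerate
        assert len(set(res.risk_group)) == 1

    def test_held_out_patient_never_sets_their_own_cutoff(self):
        # moving one patient's value across the whole range must not change
        # the number of LOOCV iterations (their value is excluded from each
        # cutoff estimate except their own assignment)
        base = np.array([1, 2, 3, 4, 10, 11, 12, 13.0])
        os_m = np.array([4, 5, 6, 7, 20, 25, 28, 30.0])
        ev = np.ones(8, int)
        res_a = loocv_cutoff_and_groups(base, os_m, ev, n_perm=50, seed=0)
        moved = base.copy()
        moved[0] = 100.0  # extreme outlier, still a non-survivor
        res_b = loocv_cutoff_and_groups(moved, os_m, ev, n_perm=50, seed=0)
        # the other patients' assignments are driven by cutoffs fit without
        # patient 0 only through the remaining data, which are identical in
        # rank structure -> their groups must not change
        np.testing.assert_array_equal(res_a.risk_group[1:4],
                                      res_b.risk_group[1:4])


class TestKaplanMeier:
    def test_matches_hand_computed_product_limit(self):
        # events at 2 and 5, censoring at 3: S = 1 -> 4/5 (t=2) -> censor ->
        # 4/5 * (1 - 1/3) = 8/15 (t=5)
        t = np.array([2.0, 3.0, 5.0, 6.0, 7.0])
        e = np.array([1, 0, 1, 0, 0])
        curves = kaplan_meier(t, e, np.zeros(5, int))
        times, surv = curves["0"]
        s_at = dict(zip(times, surv))
        assert s_at[2.0] == pytest.approx(4 / 5)
        assert s_at[5.0] == pytest.approx(4 / 5 * 2 / 3)

    def test_no_censoring_equals_empirical_survival(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        curves = kaplan_meier(t, np.ones(4, int), np.zeros(4, int))
        times, surv = curves["0"]
        s_at = dict(zip(times, surv))
        for k, tk in enumerate(t):
            assert s_at[tk] == pytest.approx(1 - (k + 1) / 4)

    def test_all_censored_stays_flat_at_one(self):
        curves = kaplan_meier([5.0, 8.0], [0, 0], [0, 0])
        _, surv = curves["0"]
        np.testing.assert_array_equal(surv, 1.0)


class TestLogrank:
    def test_statistic_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(4)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        g = rng.integers(0, 2, 40)
        ours = logrank_statistic(t, e, g)
        ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert ours == pytest.approx(ref.test_statistic, rel=1e-10)

    def test_identical_groups_give_zero_statistic_p_one(self):
        t = np.array([3.0, 5.0, 8.0, 3.0, 5.0, 8.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 1, 1, 1])
        stat, p = logrank_permutation_p(t, e, g, n_perm=200, seed=0)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_invariant_under_group_label_swap(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 30)
        e = np.ones(30, int)
        g = rng.integers(0, 2, 30)
        assert logrank_statistic(t, e, g) == pytest.approx(
            logrank_statistic(t, e, 1 - g))

    def test_strong_effect_hits_the_permutation_floor(self):
        rng = np.random.default_rng(2)
        n = 100
        t = np.concatenate([rng.exponential(3, n), rng.exponential(9, n)])
        e = np.ones(2 * n, int)
        g = np.repeat([0, 1], n)
        _, p = logrank_permutation_p(t, e, g, n_perm=1000, seed=3)
        assert p == pytest.approx(1 / 1001)

    def test_permutation_p_close_to_asymptotic_chi2(self):
        from scipy.stats import chi2

        rng = np.random.default_rng(5)
        n = 100
        t = np.concatenate([rng.exponential(5, n), rng.exponential(6.5, n)])
        e = np.ones(2 * n, int)
        g = np.repeat([0, 1], n)
        stat, p_perm = logrank_permutation_p(t, e, g, n_perm=2000, seed=6)
        p_asym = chi2.sf(stat, 1)
        assert abs(p_perm - p_asym) < 0.02

    def test_tiny_cohort_uses_exact_enumeration(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.ones(6, int)
        g = np.array([0, 0, 0, 1, 1, 1])  # C(6,3)=20 distinct assignments
        _, p = logrank_permutation_p(t, e, g, n_perm=1000, seed=0)
        assert p * 20 == pytest.approx(round(p * 20))  # exact grid


def efron_loglik(b, x, time, event):
    """Independent plain-loop Efron partial log-likelihood."""
    ll = 0.0
    ev_times = np.unique(time[event == 1])
    for td in ev_times:
        D = np.flatnonzero((time == td) & (event == 1))
        R = np.flatnonzero(time >= td)
        d = len(D)
        sR = np.exp(b * x[R]).sum()
        sD = np.exp(b * x[D]).sum()
        ll += b * x[D].sum()
        for l in range(d):
            ll -= np.log(sR - (l / d) * sD)
    return ll


class TestCox:
    t10 = np.array([2.0, 3.0, 3.0, 5.0, 7.0, 7.0, 9.0, 11.0, 14.0, 20.0])
    e10 = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0])
    v10 = np.array([0.5, 0.7, 0.6, 0.9, 0.4, 1.1, 0.8, 1.3, 0.3, 1.0])

    def test_agrees_with_brute_force_partial_likelihood_maximizer(self):
        res = cox_univariate_log2(self.v10, self.t10, self.e10, n_perm=50,
                                  seed=0)
        x = np.log2(self.v10)
        x = x - x.mean()
        sol = minimize_scalar(
            lambda b: -efron_loglik(b, x, self.t10, self.e10),
            bounds=(-10, 10), method="bounded", options={"xatol": 1e-12})
        assert res.b == pytest.approx(sol.x, abs=1e-6)

    def test_close_to_lifelines_estimate(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        res = cox_univariate_log2(self.v10, self.t10, self.e10, n_perm=50,
                                  seed=0)
        df = pd.DataFrame({"T": self.t10, "E": self.e10,
                           "x": np.log2(self.v10)})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert res.b == pytest.approx(cph.params_["x"], abs=1e-3)

    def test_hazard_ratio_is_exp_of_coefficient(self):
        res = cox_univariate_log2(self.v10, self.t10, self.e10, n_perm=50,
                                  seed=0)
        assert res.hr == np.exp(res.b)

    def test_binary_twofold_covariate_recovers_hr_two(self):
        rng = np.random.default_rng(8)
        n = 1000
        grp = rng.integers(0, 2, n)
        vals = np.where(grp == 1, 2.0, 1.0)
        t = rng.exponential(1.0 / (0.05 * np.where(grp == 1, 2.0, 1.0)))
        res = cox_univariate_log2(vals, t, np.ones(n, int), n_perm=20, seed=0)
        assert 1.8 <= res.hr <= 2.2

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate_log2(np.ones(10), self.t10, self.e10)

    def test_nonpositive_values_rejected_with_indices(self):
        v = self.v10.copy()
        v[4] = -1.0
        with pytest.raises(ValueError, match=r"\[4\]"):
            cox_univariate_log2(v, self.t10, self.e10)

    def test_gradient_vanishes_at_reported_solution(self):
        from hepwx.survival_analysis import _cox_loglik_grad_hess

        res = cox_univariate_log2(self.v10, self.t10, self.e10, n_perm=20,
                                  seed=0)
        x = np.log2(self.v10)
        x = x - x.mean()
        _, grad, _ = _cox_loglik_grad_hess(res.b, x, self.t10, self.e10)
        assert abs(grad) <= 1e-8


class TestHazardPercentChange:
    @pytest.mark.parametrize("hr,expected", [
        (21.51, 35.9), (8.418, 23.7), (10.14, 26.1), (4.213, 15.5),
    ])
    def test_tenth_step_on_log2_scale(self, hr, expected):
        assert round(hazard_percent_change(hr, 0.1, "log_scale"), 1) == expected

    def test_unit_hazard_ratio_changes_nothing(self):
        assert hazard_percent_change(1.0, 0.37, "log_scale") == pytest.approx(0.0)

    def test_one_minus_mode(self):
        assert hazard_percent_change(0.716, mode="one_minus") == pytest.approx(28.4)


class TestPermutationCalibration:
    def test_null_permutation_p_is_roughly_uniform(self):
        # small-scale calibration; the acceptance suite runs the full version
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(60):
            t = rng.exponential(12, 20)
            e = np.ones(20, int)
            g = rng.permutation(np.repeat([0, 1], 10))
            _, p = logrank_permutation_p(t, e, g, n_perm=500,
                                         seed=int(rng.integers(2**31)))
            ps.append(p)
        from scipy.stats import kstest

        d = kstest(ps, "uniform").statistic
        assert d < 0.2
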