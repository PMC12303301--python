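"""Discrimination, calibration, Brier, decision curves, recalibration."""

import numpy as np
import pandas as pd
import pytest

from hybridcox.hybrid import StackedModel, fit_stacked
from hybridcox.simulate import simulate_from_model
from hybridcox.validate import (
    bootstrap_metric,
    brier,
    calibration_in_the_large,
    calibration_slope,
    compare_models,
    decile_calibration,
    decision_curve,
    harrells_c,
    recalibrate,
    repeated_cv,
)


def brute_force_c(risk, times, events):
    """O(n^2) pair enumeration oracle for Harrell's C.

    A pair is usable iff subject j is observed to fail no later than subject
    i survives: t_j < t_i, or t_j == t_i with i censored (i is then known to
    have lived at least as long).  Ties in predicted risk score one half.
    """
    conc = ties = usable = 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if events[j] == 0:
                continue
            if not (times[j] < times[i] or (times[j] == times[i] and events[i] == 0)):
                continue
            usable += 1
            if risk[j] > risk[i]:
                conc += 1
            elif risk[j] == risk[i]:
                ties += 1
    return (conc + 0.5 * ties) / usable


class TestHarrellsC:
    def test_perfectly_anti_ordered_risks_give_one(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        assert harrells_c(np.array([4, 3, 2, 1.0]), times, np.ones(4, int)) == 1.0

    def test_hand_enumerated_six_pairs(self):
        # pairs (by event time): (1,2),(1,3),(1,4),(2,3),(2,4),(3,4)
        # concordant under risks (.9,.1,.8,.2): (1,2),(1,4),(3,4),(1,3 -> .9>.8 yes)
        c = harrells_c(np.array([0.9, 0.1, 0.8, 0.2]),
                       np.array([2.0, 4.0, 6.0, 8.0]), np.ones(4, int))
        assert c == pytest.approx(4 / 6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        risk = rng.choice(np.linspace(0, 1, 15), n)  # induces ties
        times = rng.exponential(1.0, n).round(2)  # induces tied times
        events = rng.binomial(1, 0.6, n)
        events[0] = 1
        assert harrells_c(risk, times, events) == pytest.approx(
            brute_force_c(risk, times, events), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        risk = rng.uniform(size=60)
        times = rng.exponential(1, 60)
        events = rng.binomial(1, 0.7, 60)
        events[0] = 1
        a = harrells_c(risk, times, events)
        b = harrells_c(np.exp(5 * risk) + 2, times, events)
        assert a == pytest.approx(b, abs=1e-12)

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError):
            harrells_c(np.array([0.1, 0.2]), np.array([1.0, 2.0]), np.zeros(2, int))


class TestBootstrap:
    def test_constant_metric_has_zero_width_ci(self):
        df = pd.DataFrame({"v": np.arange(50.0)})
        mean, (lo, hi) = bootstrap_metric(lambda d: 1.23, df, B=50, seed=0)
        assert mean == lo == hi == 1.23

    def test_fixed_seed_is_bit_reproducible(self):
        df = pd.DataFrame({"v": np.random.default_rng(0).normal(size=100)})
        a = bootstrap_metric(lambda d: d["v"].mean(), df, B=100, seed=7)
        b = bootstrap_metric(lambda d: d["v"].mean(), df, B=100, seed=7)
        assert a == b

    def test_percentile_ci_coverage_for_a_normal_mean(self):
        rng = np.random.default_rng(3)
        covered = 0
        reps = 100
        for r in range(reps):
            df = pd.DataFrame({"v": rng.normal(size=200)})
            _, (lo, hi) = bootstrap_metric(lambda d: d["v"].mean(), df, B=300, seed=r)
            covered += lo <= 0.0 <= hi
        assert 0.88 <= covered / reps <= 0.99

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_metric(lambda d: 0.0, pd.DataFrame({"v": [1.0]}), B=1)


class TestRepeatedCV:
    @staticmethod
    def _null_df(n=2000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "followup_years": rng.exponential(5, n),
            "event": rng.binomial(1, 0.3, n),
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
        })

    @staticmethod
    def _fit_predict(train, test):
        m = fit_stacked(train, ["a", "b"], lam=1e-4, flavor="basic")
        return m.predict_risk(test)

    def test_null_simulation_calibrates_the_harness_to_chance(self):
        vals = repeated_cv(self._null_df(), self._fit_predict, harrells_c,
                           k=5, repeats=3, seed=4)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_reproducible_pair_of_repeats(self):
        df = self._null_df(600, seed=1)
        a = repeated_cv(df, self._fit_predict, harrells_c, k=4, repeats=2, seed=9)
        b = repeated_cv(df, self._fit_predict, harrells_c, k=4, repeats=2, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_more_folds_than_events_is_an_error(self):
        df = self._null_df(40, seed=2)
        df["event"] = 0
        df.loc[:2, "event"] = 1
        with pytest.raises(ValueError, match="events"):
            repeated_cv(df, self._fit_predict, harrells_c, k=10, repeats=1, seed=0)


class TestDecileCalibration:
    def test_hand_ranked_groups_on_100_subjects(self):
        risk = np.linspace(0.01, 0.99, 100)
        times = np.full(100, 20.0)
        events = np.zeros(100, int)
        table = decile_calibration(risk, times, events, horizon=10).table
        assert len(table) == 10
        assert (table["n"] == 10).all()
        # lowest decile = first ten ranked subjects
        assert table["mean_predicted"].iloc[0] == pytest.approx(risk[:10].mean())
        assert table["mean_predicted"].is_monotonic_increasing

    def test_self_consistent_generator_calibrates_within_two_points(self):
        rng = np.random.default_rng(0)
        n = 50_000
        risk = rng.uniform(0.02, 0.5, n)
        events = rng.uniform(size=n) < risk
        times = np.where(events, rng.uniform(0.1, 9.9, n), 20.0)
        table = decile_calibration(risk, times, events.astype(int), horizon=10).table
        assert (abs(table["mean_predicted"] - table["observed"]) <= 0.02).all()

    def test_constant_risk_collapses_to_single_group_and_slope_errors(self):
        risk = np.full(100, 0.3)
        times = np.full(100, 5.0)
        events = np.ones(100, int)
        with pytest.warns(UserWarning, match="distinct"):
            table = decile_calibration(risk, times, events, horizon=10)
        assert len(table) == 1
        with pytest.raises(ValueError, match="degenerate"):
            calibration_slope(table)


class TestCalibrationScalars:
    def test_identity_and_double_slope(self):
        base = decile_calibration(np.linspace(0.05, 0.5, 100), np.full(100, 20.0),
                                  np.zeros(100, int), horizon=10)
        t = base.table.copy()
        t["observed"] = t["mean_predicted"]
        base.table = t
        assert calibration_slope(base) == pytest.approx(1.0)
        t["observed"] = 2 * t["mean_predicted"]
        assert calibration_slope(base) == pytest.approx(2.0)

    def test_three_point_hand_least_squares(self):
        table = decile_calibration(np.repeat([0.1, 0.2, 0.3], 10), np.full(30, 20.0),
                                   np.zeros(30, int), horizon=10)
        t = table.table.copy()
        t["observed"] = [0.12, 0.19, 0.33]
        table.table = t
        assert calibration_slope(table) == pytest.approx(1.05)

    def test_citl_shift_identity_without_censoring(self):
        rng = np.random.default_rng(5)
        n = 20_000
        p = rng.uniform(0.1, 0.4, n)
        events = (rng.uniform(size=n) < p).astype(int)
        times = np.where(events, 5.0, 20.0)
        citl = calibration_in_the_large(p + 0.05, times, events, horizon=10)
        assert citl == pytest.approx(-0.05, abs=0.01)

    def test_citl_simple_counts(self):
        # 30% observed events, mean prediction 0.2 -> CITL = +0.1
        events = np.r_[np.ones(3, int), np.zeros(7, int)]
        times = np.where(events == 1, 4.0, 20.0)
        citl = calibration_in_the_large(np.full(10, 0.2), times, events, horizon=10)
        assert citl == pytest.approx(0.1)


class TestBrier:
    def test_perfect_binary_predictions_score_zero(self):
        events = np.array([1, 1, 0, 0])
        times = np.array([1.0, 2.0, 20.0, 20.0])
        assert brier(events.astype(float), times, events, horizon=10) == 0.0

    def test_uninformative_half_predictions_score_quarter(self):
        events = np.array([1, 0, 1, 0])
        times = np.array([1.0, 20.0, 3.0, 20.0])
        assert brier(np.full(4, 0.5), times, events, horizon=10) == pytest.approx(0.25)

    def test_four_subject_hand_ipcw_computation(self):
        # times (2,5,8,12), events (1,0,1,0), horizon 10, risks (.8,.5,.4,.1)
        # censoring KM: drop of 1/3 after t=5 -> G=2/3 beyond 5
        # contributions: (1-.8)^2/1, 0 (censored early), (1-.4)^2/(2/3), .1^2/(2/3)
        val = brier(np.array([0.8, 0.5, 0.4, 0.1]),
                    np.array([2.0, 5.0, 8.0, 12.0]),
                    np.array([1, 0, 1, 0]), horizon=10)
        assert val == pytest.approx((0.04 + 0.54 + 0.015) / 4)

    def test_reduces_to_mean_squared_error_without_censoring(self):
        rng = np.random.default_rng(2)
        n = 500
        risk = rng.uniform(size=n)
        events = rng.binomial(1, 0.4, n)
        times = np.where(events == 1, rng.uniform(0.1, 9.9, n), rng.uniform(10.01, 30, n))
        events_all = np.ones(n, int)  # everyone's status known at the horizon
        outcome = (times <= 10).astype(float)
        expected = np.mean((outcome - risk) ** 2)
        assert brier(risk, times, events_all, horizon=10) == pytest.approx(expected)

    def test_matches_independent_ipcw_implementation(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        from sksurv.util import Surv

        rng = np.random.default_rng(4)
        n = 300
        times = rng.exponential(8, n)
        events = rng.binomial(1, 0.6, n)
        risk = rng.uniform(size=n)
        horizon = np.quantile(times, 0.6)
        y = Surv.from_arrays(event=events.astype(bool), time=times)
        _, (expected,) = sksurv_metrics.brier_score(y, y, 1 - risk[None].T @ np.ones((1, 1)), [horizon])
        assert brier(risk, times, events, horizon=horizon) == pytest.approx(expected, abs=1e-10)


class TestDecisionCurve:
    def test_hand_net_benefit_example(self):
        # 10 subjects, 4 events, 5 flagged of whom 3 are true positives
        risk = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.1, 0.1, 0.1, 0.1, 0.1])
        events = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
        times = np.where(events == 1, 5.0, 20.0)
        curve = decision_curve(risk, times, events, horizon=10, thresholds=[0.2]).table
        assert curve["nb_model"].iloc[0] == pytest.approx(0.3 - 0.2 * 0.25)

    def test_treat_none_is_identically_zero(self):
        rng = np.random.default_rng(0)
        curve = decision_curve(rng.uniform(size=50), rng.exponential(8, 50),
                               rng.binomial(1, 0.5, 50), horizon=5).table
        assert (curve["nb_none"] == 0).all()

    def test_small_threshold_limit_approaches_prevalence(self):
        events = np.r_[np.ones(30, int), np.zeros(70, int)]
        times = np.where(events == 1, 5.0, 20.0)
        risk = np.full(100, 0.9)
        curve = decision_curve(risk, times, events, horizon=10, thresholds=[1e-4]).table
        assert curve["nb_model"].iloc[0] == pytest.approx(0.3, abs=1e-3)
        assert curve["nb_all"].iloc[0] == pytest.approx(0.3, abs=1e-3)

    def test_treat_all_closed_form(self):
        events = np.r_[np.ones(40, int), np.zeros(60, int)]
        times = np.where(events == 1, 5.0, 20.0)
        curve = decision_curve(np.full(100, 0.99), times, events,
                               horizon=10, thresholds=[0.25]).table
        expected = 0.4 - 0.6 * 0.25 / 0.75
        assert curve["nb_all"].iloc[0] == pytest.approx(expected)
        assert curve["nb_model"].iloc[0] == pytest.approx(expected)

    def test_threshold_one_excluded_from_grid(self):
        curve = decision_curve(np.array([0.5, 0.5]), np.array([5.0, 20.0]),
                               np.array([1, 0]), horizon=10, thresholds=[0.5, 1.0]).table
        assert curve["threshold"].tolist() == [0.5]


def _simple_model(beta=0.6, lam=1e-4, n=20_000, seed=3):
    """A small well-specified Cox model fitted on its own kind of data."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    T = 12.0 * np.exp(-beta * x / 1.1) * rng.weibull(1.1, n)
    C = np.minimum(rng.exponential(15, n), 14.0)
    df = pd.DataFrame({"followup_years": np.minimum(T, C),
                       "event": (T <= C).astype(int), "x": x})
    model = fit_stacked(df, ["x"], lam=lam, flavor="basic")
    return model, df


class TestRecalibration:
    def test_self_consistency_near_identity_update(self):
        model, _ = _simple_model()
        target = simulate_from_model(model, pd.DataFrame(
            {"x": np.random.default_rng(10).normal(size=30_000)}), seed=11)
        result, _ = recalibrate(model, target, horizon=10)
        assert result.slope_multiplier == pytest.approx(1.0, abs=0.05)
        assert abs(result.intercept_shift) < 0.1

    def test_doubled_baseline_hazard_is_recovered(self):
        model, _ = _simple_model()
        doubled = StackedModel.from_dict(model.to_dict())
        doubled.baseline_survival = doubled.baseline_survival**2  # H0 -> 2 H0
        target = simulate_from_model(doubled, pd.DataFrame(
            {"x": np.random.default_rng(12).normal(size=30_000)}), seed=13)
        result, updated = recalibrate(model, target, horizon=10)
        assert result.intercept_shift == pytest.approx(np.log(2), rel=0.10)
        assert abs(result.after_citl) < abs(result.before_citl)
        assert result.accepted

    def test_acceptance_rule_is_the_two_criterion_invariant(self):
        model, _ = _simple_model(n=5_000)
        target = simulate_from_model(model, pd.DataFrame(
            {"x": np.random.default_rng(14).normal(size=5_000)}), seed=15)
        result, _ = recalibrate(model, target, horizon=10)
        expected = (abs(result.after_slope - 1) <= abs(result.before_slope - 1)
                    and abs(result.after_citl) <= abs(result.before_citl))
        assert result.accepted == expected

    def test_no_events_rejected(self):
        model, df = _simple_model(n=2_000)
        df = df.assign(event=0)
        with pytest.raises(ValueError, match="no events"):
            recalibrate(model, df, horizon=10)


class TestCompareModels:
    def test_single_model_row_consistent_with_direct_metrics(self):
        model, df = _simple_model(n=3_000)
        table, curves = compare_models({"m": model}, df, horizon=10, B=50, seed=1)
        risk = model.predict_risk(df, horizon=10)
        t, e = df["followup_years"].to_numpy(), df["event"].to_numpy()
        assert table["brier"].iloc[0] == pytest.approx(brier(risk, t, e, 10))
        assert table["citl"].iloc[0] == pytest.approx(
            calibration_in_the_large(risk, t, e, 10))
        assert "m" in curves

    def test_informative_score_beats_noise_column(self):
        model, df = _simple_model(n=3_000)
        rng = np.random.default_rng(0)
        table, _ = compare_models(
            {"model": model, "noise": rng.uniform(size=len(df))},
            df, horizon=10, B=50, seed=2,
        )
        t = table.set_index("model")
        assert t.loc["model", "c"] > t.loc["noise", "c"] + 0.05

    def test_fixed_seed_reproducible(self):
        model, df = _simple_model(n=2_000)
        a, _ = compare_models({"m": model}, df, B=40, seed=5)
        b, _ = compare_models({"m": model}, df, B=40, seed=5)
        pd.testing.assert_frame_equal(a, b)
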