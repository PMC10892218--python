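"""ARIMA selection, counterfactual forecasting and observed-vs-predicted
comparison."""

import datetime as dt
import warnings

import numpy as np
import pytest

from adtrends.claims import PopulationTable, StudyCalendar
from adtrends.episodes import TreatmentEpisode
from adtrends.its import (
    ArimaSpec,
    compare,
    fit_pre_period,
    forecast_counterfactual,
    split_series,
)
from adtrends.prevalence import weekly_prevalence


def make_series(calendar, n_active_per_week=None, n=50):
    """Weekly series with a constant (or given) number of active users."""
    pop = PopulationTable(total={y: 100_000 for y in range(2018, 2022)})
    eps = {f"S{i}": [TreatmentEpisode(f"S{i}", "N06A", calendar.index_start,
                                      calendar.index_end, 1)]
           for i in range(n)}
    return weekly_prevalence(eps, "N06A", calendar, pop)


class TestSplitSeries:
    def test_default_segments(self, calendar):
        series = make_series(calendar)
        pre, post = split_series(series)
        assert (len(pre), len(post)) == (102, 86)  # 114 - 12 burn-in, 86

    def test_no_burn_in(self):
        cal = StudyCalendar(burn_in_weeks=0)
        pre, post = split_series(make_series(cal))
        assert (len(pre), len(post)) == (114, 86)

    def test_interruption_in_final_week_warns(self):
        cal = StudyCalendar(index_start=dt.date(2018, 1, 1),
                            interruption_date=dt.date(2018, 6, 25),
                            index_end=dt.date(2018, 7, 1), burn_in_weeks=0)
        assert cal.n_weeks == 25 and cal.interruption_week == 26
        with pytest.warns(UserWarning, match="empty"):
            pre, post = split_series(make_series(cal))
        assert len(post) == 0


class TestFitPrePeriod:
    def test_white_noise_selects_level_stationary_model(self):
        rng = np.random.default_rng(42)
        y = 10 + rng.normal(0, 1, 150)
        fitted, res = fit_pre_period(y)
        assert fitted.order[1] == 0
        fc = forecast_counterfactual(res, 20)
        assert fc.predicted == pytest.approx(np.full(20, y.mean()), abs=0.5)

    def test_random_walk_selects_differencing(self):
        rng = np.random.default_rng(7)
        y = 100 + np.cumsum(rng.normal(0, 1, 200))  # positive random walk
        fitted, res = fit_pre_period(y)
        assert fitted.order[1] >= 1
        fc = forecast_counterfactual(res, 10)
        # any estimated drift is O(sigma/sqrt(n)) per step: forecast stays
        # within a few units of the last value
        assert abs(fc.predicted[-1] - y[-1]) < 3.0

    def test_ar1_coefficient_recovery(self):
        """Mean phi-hat over 200 simulated AR(1) series is close to 0.6."""
        rng = np.random.default_rng(123)
        phis = []
        spec = ArimaSpec(order=(1, 0, 0), with_constant=False, selection="fixed")
        for _ in range(200):
            e = rng.normal(0, 1, 300)
            y = np.empty(300)
            y[0] = e[0]
            for t in range(1, 300):
                y[t] = 0.6 * y[t - 1] + e[t]
            fitted, _ = fit_pre_period(y, spec)
            phis.append(fitted.params["ar.L1"])
        assert abs(np.mean(phis) - 0.6) < 0.05

    def test_non_finite_values_rejected(self):
        y = np.ones(60)
        y[10] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_pre_period(y)

    def test_too_short_for_auto_selection(self):
        with pytest.raises(ValueError, match="30"):
            fit_pre_period(np.ones(10))

    def test_selection_is_deterministic(self):
        rng = np.random.default_rng(5)
        y = np.cumsum(rng.normal(0.2, 1, 102)) + 50
        f1, _ = fit_pre_period(y)
        f2, _ = fit_pre_period(y)
        assert f1.order == f2.order and f1.aicc == f2.aicc


class TestForecast:
    def test_mean_model_flat_forecast_constant_width(self):
        rng = np.random.default_rng(3)
        y = 5 + rng.normal(0, 1, 120)
        spec = ArimaSpec(order=(0, 0, 0), with_constant=True, selection="fixed")
        _, res = fit_pre_period(y, spec)
        fc = forecast_counterfactual(res, 30)
        widths = fc.pi_high - fc.pi_low
        assert np.allclose(fc.predicted, fc.predicted[0])
        assert np.allclose(widths, widths[0])

    def test_random_walk_interval_grows_like_sqrt_h(self):
        rng = np.random.default_rng(4)
        y = np.cumsum(rng.normal(0, 1, 300)) + 100
        spec = ArimaSpec(order=(0, 1, 0), with_constant=False, selection="fixed")
        _, res = fit_pre_period(y, spec)
        fc = forecast_counterfactual(res, 100)
        assert np.allclose(fc.predicted, y[-1], atol=1e-6)
        widths = fc.pi_high - fc.pi_low
        assert widths[99] / widths[0] == pytest.approx(10.0, rel=0.01)

    def test_zero_horizon_rejected(self):
        rng = np.random.default_rng(3)
        _, res = fit_pre_period(5 + rng.normal(0, 1, 60))
        with pytest.raises(ValueError):
            forecast_counterfactual(res, 0)

    def test_prediction_interval_coverage_ar1(self):
        """95% PI covers the 8-step-ahead future ~95% of the time."""
        rng = np.random.default_rng(99)
        n, h, hits = 300, 8, 0
        reps = 400
        spec = ArimaSpec(order=(1, 0, 0), with_constant=True, selection="fixed")
        for _ in range(reps):
            e = rng.normal(0, 1, n + h)
            y = np.empty(n + h)
            y[0] = 50 + e[0]
            for t in range(1, n + h):
                y[t] = 50 + 0.6 * (y[t - 1] - 50) + e[t]
            _, res = fit_pre_period(y[:n], spec)
            fc = forecast_counterfactual(res, h)
            hits += fc.pi_low[-1] <= y[-1] <= fc.pi_high[-1]
        assert 0.93 <= hits / reps <= 0.97


class TestCompare:
    def test_identical_series_null_result(self):
        obs = np.array([10.0, 11.0, 12.0])
        from adtrends.its import Forecast
        fc = Forecast(obs.copy(), obs - 1, obs + 1, 0.05)
        result = compare(obs, fc, [100_000] * 3, first_week=115)
        assert np.allclose(result.diff_per_10k, 0)
        assert all(o.odds_ratio == pytest.approx(1.0) for o in result.odds_ratios)
        assert result.first_persistent_week is None

    def test_reconstructed_counts_and_or(self):
        """137.9 vs 112.9 per 10k over 94,864 people: diff 25, OR ~1.22."""
        from adtrends.its import Forecast
        obs = np.array([137.9])
        fc = Forecast(np.array([112.9]), np.array([100.0]), np.array([125.0]), 0.05)
        result = compare(obs, fc, [94_864], first_week=170)
        assert result.diff_per_10k[0] == pytest.approx(25.0)
        orr = result.odds_ratios[0]
        assert (orr.a, orr.c) == (1308, 1071)
        # (1308 * 93793) / (93556 * 1071)
        assert orr.odds_ratio == pytest.approx(1.2244, abs=1e-3)

    def test_spike_week_is_argmax(self):
        from adtrends.its import Forecast
        pred = np.full(10, 20.0)
        obs = pred.copy()
        obs[6] += 9.0
        fc = Forecast(pred, pred - 1, pred + 1, 0.05)
        result = compare(obs, fc, [100_000] * 10, first_week=115)
        assert result.max_diff_week == 121
        assert result.first_persistent_week is None

    def test_length_mismatch_rejected(self):
        from adtrends.its import Forecast
        fc = Forecast(np.ones(3), np.zeros(3), np.ones(3) * 2, 0.05)
        with pytest.raises(ValueError):
            compare(np.ones(4), fc, [1000] * 4, first_week=115)
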