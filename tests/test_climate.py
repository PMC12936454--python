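"""SPEI construction, calibration behaviour and event classification."""

import numpy as np
import pandas as pd
import pytest

import agrocycle as ac
from agrocycle.climate import (
    EventThresholds,
    GaussianParams,
    LogLogisticParams,
    fit_log_logistic,
)


def _weather(months=360, precip=60.0, pet=50.0, seed=0):
    dates = pd.date_range("1981-01-01", periods=months * 30, freq="D")
    # trim to whole months of the real calendar
    end = dates[-1] - pd.offsets.MonthBegin(0)
    dates = pd.date_range("1981-01-01", end - pd.Timedelta(days=1), freq="D")
    rng = np.random.default_rng(seed)
    n = len(dates)
    return pd.DataFrame(
        {
            "date": dates,
            "tmin": 5.0,
            "tmax": 15.0,
            "precip": np.maximum(rng.normal(precip, 20, n), 0) / 30.0,
            "pet": pet / 30.0,
        }
    )


class TestMonthlyBalance:
    def test_precip_equal_pet_gives_zero(self):
        dates = pd.date_range("1990-01-01", "1990-12-31", freq="D")
        w = pd.DataFrame({"date": dates, "precip": 2.0, "pet": 2.0})
        d = ac.monthly_balance(w)
        assert np.allclose(d.to_numpy(), 0.0)
        assert len(d) == 12

    def test_single_month_arithmetic(self):
        dates = pd.date_range("1990-06-01", "1990-06-30", freq="D")
        w = pd.DataFrame({"date": dates, "precip": 2.0, "pet": 100.0 / 30})
        assert ac.monthly_balance(w).iloc[0] == pytest.approx(60.0 - 100.0)

    def test_gap_in_series_rejected(self):
        dates = pd.date_range("1990-01-01", "1990-12-31", freq="D")
        w = pd.DataFrame({"date": dates, "precip": 1.0, "pet": 1.0})
        w = w.drop(index=40)
        with pytest.raises(ValueError):
            ac.monthly_balance(w)

    def test_partial_month_rejected(self):
        dates = pd.date_range("1990-01-05", "1990-12-31", freq="D")
        w = pd.DataFrame({"date": dates, "precip": 1.0, "pet": 1.0})
        with pytest.raises(ValueError):
            ac.monthly_balance(w)

    def test_rolling_three_month_window_sums_adjacent_months(self):
        idx = pd.period_range("1990-01", periods=12, freq="M")
        d = pd.Series(np.arange(12, dtype=float), index=idx)
        rolled = ac.rolling_balance(d, 3)
        assert np.isnan(rolled.iloc[0]) and np.isnan(rolled.iloc[1])
        expected = [d.iloc[i - 2] + d.iloc[i - 1] + d.iloc[i] for i in range(2, 12)]
        np.testing.assert_allclose(rolled.iloc[2:].to_numpy(), expected)


@pytest.fixture(scope="module")
def spei(hist_weather):
    return ac.fit_spei(ac.monthly_balance(hist_weather))


class TestSpeiFit:
    def test_calibration_window_is_roughly_standard_normal(self, spei):
        v = spei.values.to_numpy()
        assert abs(np.mean(v)) < 0.1
        assert 0.85 <= np.std(v) <= 1.15

    def test_fitted_median_maps_to_zero(self, spei):
        for m, par in spei.coefficients.items():
            if isinstance(par, LogLogisticParams):
                med = par.gamma + par.alpha  # F(gamma + alpha) = 1/2
            else:
                med = par.mu
            assert par.cdf(np.array([med]))[0] == pytest.approx(0.5)

    def test_uniformly_drier_series_shifts_negative(self, hist_weather):
        d = ac.monthly_balance(hist_weather)
        base = ac.fit_spei(d)
        drier = ac.fit_spei(d - 40.0, coefficients=base.coefficients)
        assert drier.values.mean() < base.values.mean() - 0.3

    def test_future_series_reuses_historical_coefficients(self, hist_weather):
        d = ac.monthly_balance(hist_weather)
        base = ac.fit_spei(d)
        reused = ac.fit_spei(d, coefficients=base.coefficients)
        pd.testing.assert_series_equal(base.values, reused.values)
        assert reused.coefficients is base.coefficients

    def test_short_calibration_window_rejected(self):
        idx = pd.period_range("1990-01", periods=120, freq="M")
        rng = np.random.default_rng(0)
        d = pd.Series(rng.normal(0, 30, 120), index=idx)
        with pytest.raises(ValueError):
            ac.fit_spei(d)  # only 10 years

    def test_degenerate_month_rejected(self):
        idx = pd.period_range("1990-01", periods=300, freq="M")
        d = pd.Series(5.0, index=idx)
        with pytest.raises(ValueError):
            ac.fit_spei(d)

    def test_pwm_fit_recovers_known_parameters(self):
        from scipy.stats import fisk

        x = fisk.rvs(3.2, loc=-10, scale=40, size=5000,
                     random_state=np.random.default_rng(0))
        p = fit_log_logistic(x)
        assert p.beta == pytest.approx(3.2, rel=0.1)
        assert p.alpha == pytest.approx(40.0, rel=0.1)
        assert p.gamma == pytest.approx(-10.0, abs=4.0)


@pytest.fixture(scope="module")
def thresholds():
    return EventThresholds(-1.2, -0.6, 0.6, 1.2)


class TestClassification:
    @pytest.mark.parametrize(
        "value,label",
        [
            (-2.0, "extreme_dry"),
            (-1.2, "extreme_dry"),  # boundary goes to the extreme class
            (-0.9, "moderate_dry"),
            (-0.6, "moderate_dry"),
            (0.0, "normal"),
            (0.6, "moderate_wet"),
            (0.9, "moderate_wet"),
            (1.2, "extreme_wet"),
            (2.5, "extreme_wet"),
        ],
    )
    def test_five_class_labels_with_extreme_ties(self, thresholds, value, label):
        assert ac.classify_value(value, thresholds) == label

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            EventThresholds(0.5, -0.5, 0.2, 1.0)

    def test_class_frequencies_on_calibration_window(self, hist_weather):
        spei = ac.fit_spei(ac.monthly_balance(hist_weather))
        seasonal = ac.seasonal_spei(spei, month=5).to_numpy()
        thr = ac.event_thresholds(seasonal)
        labels = ac.classify_seasons(seasonal, thr)
        n = len(labels)
        freq = {lab: (labels == lab).sum() / n for lab in np.unique(labels)}
        assert freq.get("extreme_dry", 0) == pytest.approx(0.10, abs=2 / n)
        assert freq.get("extreme_wet", 0) == pytest.approx(0.10, abs=2 / n)
        assert freq.get("moderate_dry", 0) == pytest.approx(0.15, abs=2 / n)
        assert freq.get("moderate_wet", 0) == pytest.approx(0.15, abs=2 / n)
        assert freq.get("normal", 0) == pytest.approx(0.50, abs=3 / n)

    def test_labels_invariant_to_appending_future_data(self, hist_weather):
        """No recalibration leakage: historical labels never change."""
        spei = ac.fit_spei(ac.monthly_balance(hist_weather))
        seasonal = ac.seasonal_spei(spei, month=5)
        thr = ac.event_thresholds(seasonal.to_numpy())
        before = ac.classify_seasons(seasonal.to_numpy(), thr)
        # a drier 'future' standardized with the same coefficients
        future = ac.fit_spei(
            ac.monthly_balance(hist_weather) - 25.0,
            coefficients=spei.coefficients,
        )
        after = ac.classify_seasons(seasonal.to_numpy(), thr)
        assert list(before) == list(after)
        assert ac.seasonal_spei(future, 5).mean() < seasonal.mean()
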