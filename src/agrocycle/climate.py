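"""SPEI-3 drought index and five-class climatic-event classification.

The Standardized Precipitation-Evapotranspiration Index aggregates the
monthly climatic water balance D = P - PET over a rolling window (here
3 months), fits a three-parameter log-logistic distribution per calendar
month on a historical calibration window using unbiased
probability-weighted moments, and maps the cumulative probability
through the standard normal quantile function.  Future-scenario series
are standardized with the *same* calibration coefficients, so events are
always judged against the historical climate.

Wheat growing seasons are characterized by the SPEI-3 value dated May
(the March-May window preceding flowering) and classified against the
historical per-site quantiles q0.1 / q0.25 / q0.75 / q0.9 into
extreme_dry, moderate_dry, normal, moderate_wet, extreme_wet; values on
a threshold go to the more extreme class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.stats import norm

EVENT_LABELS = (
    "extreme_dry",
    "moderate_dry",
    "normal",
    "moderate_wet",
    "extreme_wet",
)

_PROB_EPS = 1e-6


def monthly_balance(weather: pd.DataFrame) -> pd.Series:
    """Calendar-month sums of P - PET (mm) from a gap-free daily series."""
    dates = weather["date"]
    if len(dates) == 0:
        raise ValueError("empty weather series")
    deltas = dates.diff().dropna()
    if not (deltas == pd.Timedelta(days=1)).all():
        raise ValueError("daily weather series has gaps")
    first, last = dates.iloc[0], dates.iloc[-1]
    if first.day != 1 or (last + pd.Timedelta(days=1)).day != 1:
        raise ValueError("weather series must cover complete months")
    d = (weather["precip"] - weather["pet"]).to_frame("d")
    d["period"] = dates.dt.to_period("M").to_numpy()
    out = d.groupby("period")["d"].sum()
    out.index.name = "month"
    return out


def rolling_balance(d_monthly: pd.Series, window: int = 3) -> pd.Series:
    """Rolling ``window``-month sums; the first window-1 values are NaN."""
    return d_monthly.rolling(window).sum()


@dataclass(frozen=True)
class LogLogisticParams:
    """Three-parameter log-logistic: scale alpha, shape beta, location gamma."""

    alpha: float
    beta: float
    gamma: float

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(
                x > self.gamma,
                1.0 / (1.0 + (self.alpha / (x - self.gamma)) ** self.beta),
                0.0,
            )
        return f


@dataclass(frozen=True)
class GaussianParams:
    """Normal fallback for months whose PWM log-logistic fit is inadmissible.

    The log-logistic requires a right-skewed sample (shape beta > 1); for
    near-symmetric or left-skewed monthly balances the moment estimator
    can leave that domain, in which case a plain Gaussian standardization
    keeps the index well-behaved.
    """

    mu: float
    sd: float

    def cdf(self, x: np.ndarray) -> np.ndarray:
        return norm.cdf(np.asarray(x, dtype=float), loc=self.mu, scale=self.sd)


MonthlyDistribution = LogLogisticParams | GaussianParams


@dataclass(frozen=True)
class SpeiSeries:
    """Monthly SPEI values plus the calibration coefficients that made them."""

    values: pd.Series  # indexed by monthly Period
    coefficients: dict[int, MonthlyDistribution]  # per calendar month
    window: int = 3
    uid: int | None = None
    scenario: str | None = None


def _unbiased_pwm(x: np.ndarray) -> tuple[float, float, float]:
    """Unbiased probability-weighted moments w0, w1, w2 of E[X (1-F)^s]."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    i = np.arange(1, n + 1)
    w0 = x.mean()
    w1 = np.sum((n - i) / (n - 1) * x) / n
    w2 = np.sum((n - i) * (n - i - 1) / ((n - 1) * (n - 2)) * x) / n
    return float(w0), float(w1), float(w2)


def fit_log_logistic(x: np.ndarray) -> LogLogisticParams:
    """Fit by unbiased PWMs (the standard SPEI fitting procedure)."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values to fit the distribution")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) water balance sample")
    w0, w1, w2 = _unbiased_pwm(x)
    beta = (2 * w1 - w0) / (6 * w1 - w0 - 6 * w2)
    if not np.isfinite(beta) or beta <= 1.05:
        raise ValueError("PWM shape estimate outside the log-logistic domain")
    g = gamma_fn(1 + 1 / beta) * gamma_fn(1 - 1 / beta)
    alpha = (w0 - 2 * w1) * beta / g
    gamma0 = w0 - alpha * g
    return LogLogisticParams(alpha=alpha, beta=beta, gamma=gamma0)


def fit_month_distribution(x: np.ndarray) -> MonthlyDistribution:
    """Log-logistic by PWM, falling back to a Gaussian when inadmissible."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) water balance sample")
    try:
        return fit_log_logistic(x)
    except ValueError as err:
        if "degenerate" in str(err) or "at least" in str(err):
            raise
        return GaussianParams(mu=float(x.mean()), sd=float(x.std(ddof=1)))


def fit_spei(
    d_monthly: pd.Series,
    window: int = 3,
    calibration_window: tuple[int, int] | None = None,
    coefficients: dict[int, MonthlyDistribution] | None = None,
    uid: int | None = None,
    scenario: str | None = None,
) -> SpeiSeries:
    """Standardize a monthly water-balance series into SPEI values.

    ``calibration_window`` is an inclusive ``(first_year, last_year)``
    span (>= 20 years) used to fit the per-calendar-month distributions;
    by default the whole series is used.  Passing ``coefficients``
    (e.g. from a historical fit) standardizes a future series without
    recalibration.
    """
    if not isinstance(d_monthly.index, pd.PeriodIndex):
        raise TypeError("d_monthly must have a monthly PeriodIndex")
    rolled = rolling_balance(d_monthly, window).dropna()

    if coefficients is None:
        if calibration_window is None:
            calib = rolled
        else:
            y0, y1 = calibration_window
            calib = rolled[(rolled.index.year >= y0) & (rolled.index.year <= y1)]
        n_years = calib.index.year.nunique()
        if n_years < 20:
            raise ValueError(
                f"calibration window must span >= 20 years, got {n_years}"
            )
        coefficients = {
            m: fit_month_distribution(calib[calib.index.month == m].to_numpy())
            for m in range(1, 13)
        }

    spei = pd.Series(index=rolled.index, dtype=float)
    for m in range(1, 13):
        mask = rolled.index.month == m
        if not mask.any():
            continue
        f = coefficients[m].cdf(rolled[mask].to_numpy())
        spei[mask] = norm.ppf(np.clip(f, _PROB_EPS, 1 - _PROB_EPS))
    return SpeiSeries(
        values=spei, coefficients=coefficients, window=window,
        uid=uid, scenario=scenario,
    )


def seasonal_spei(spei: SpeiSeries, month: int = 5) -> pd.Series:
    """The SPEI value dated ``month`` for each year (year-indexed)."""
    vals = spei.values[spei.values.index.month == month]
    out = pd.Series(vals.to_numpy(), index=vals.index.year)
    out.index.name = "year"
    return out


@dataclass(frozen=True)
class EventThresholds:
    """Historical per-site SPEI quantiles delimiting the five classes."""

    q10: float
    q25: float
    q75: float
    q90: float

    def __post_init__(self) -> None:
        if not (self.q10 < self.q25 < self.q75 < self.q90):
            raise ValueError("quantiles must be strictly increasing")


def event_thresholds(
    historical_values, quantiles=(0.1, 0.25, 0.75, 0.9)
) -> EventThresholds:
    """Empirical quantiles of the historical seasonal SPEI for one site."""
    v = np.asarray(historical_values, dtype=float)
    q = np.quantile(v, quantiles)
    return EventThresholds(*map(float, q))


def classify_value(x: float, thr: EventThresholds) -> str:
    """Five-class label; threshold ties go to the more extreme class."""
    if x <= thr.q10:
        return "extreme_dry"
    if x <= thr.q25:
        return "moderate_dry"
    if x >= thr.q90:
        return "extreme_wet"
    if x >= thr.q75:
        return "moderate_wet"
    return "normal"


def classify_seasons(values, thr: EventThresholds) -> np.ndarray:
    """Vectorized five-class labels for seasonal SPEI values."""
    return np.array([classify_value(float(x), thr) for x in np.asarray(values)])
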