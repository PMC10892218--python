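"""ARIMA interrupted time-series counterfactual.

The weekly prevalence series is split at the interruption into a
pre-interruption segment (after dropping the burn-in weeks, whose episode
ascertainment lacks look-back) and a post segment.  An ARIMA model is
selected on the pre segment by a stepwise search minimising the
small-sample-corrected information criterion (AICc), in the spirit of the
Hyndman-Khandakar auto-ARIMA algorithm:

* the regular differencing order ``d`` comes from repeated KPSS tests;
* seasonal terms (period ``s``, default 52) are searched only when the
  series contains at least two full seasonal cycles plus a margin — shorter
  series cannot identify them and the search collapses to the non-seasonal
  family, as auto-ARIMA implementations conventionally do;
* from a set of starting orders, neighbours (p +- 1, q +- 1, constant
  toggled) are explored until no neighbour improves the AICc.

The fitted model is frozen and forecast over the whole post segment
(no re-fitting inside the interruption window); normal-theory prediction
intervals accompany the forecast.  Fitting is deterministic given the
series: no stochastic restarts are used.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm as _norm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, ValueWarning
from statsmodels.tsa.statespace.sarimax import SARIMAX
from statsmodels.tsa.stattools import kpss

from .prevalence import PER_10K, PrevalenceSeries, TwoByTwoResult, round_half_up, two_by_two
from .claims import StudyCalendar, label_of_week

MAX_P = MAX_Q = 5
MAX_D = 2
MAX_SP = MAX_SQ = 2
MAX_SD = 1


@dataclass(frozen=True)
class ArimaSpec:
    """Model order request plus, after fitting, the estimates.

    ``trend`` is the deterministic component: ``"n"`` none, ``"c"`` a
    constant (a drift once the series is differenced), ``"ct"`` constant
    plus linear time trend (candidates for undifferenced fits only).
    """

    order: tuple[int, int, int] | None = None
    seasonal_order: tuple[int, int, int] = (0, 0, 0)
    seasonal_period: int = 52
    trend: str | None = None
    with_constant: bool | None = None
    selection: str = "auto_stepwise_aicc"  # or "fixed"
    # variance-stabilizing transform applied before fitting in run_its: the
    # weekly numerators are counts, so their innovation variance scales
    # with the level; the square root approximately stabilizes it
    transform: str = "sqrt"  # "none" | "sqrt" | "log"
    # populated by fit_pre_period
    params: Mapping[str, float] | None = None
    param_se: Mapping[str, float] | None = None
    sigma2: float | None = None
    aicc: float | None = None
    n_obs: int | None = None


class ArimaFitError(RuntimeError):
    pass


def split_series(
    series: PrevalenceSeries, calendar: StudyCalendar | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pre- and post-interruption rate segments.

    Burn-in weeks are dropped from the pre segment only; the post segment
    starts at the interruption week and runs to the end of the calendar.
    """
    cal = calendar or series.calendar
    rates = series.rates
    if len(rates) != cal.n_weeks:
        raise ValueError("series length does not match the calendar")
    cut = cal.interruption_week - 1  # 0-based index of first post week
    if cut > len(rates):
        raise ValueError("interruption lies outside the series")
    pre = rates[cal.burn_in_weeks:cut]
    post = rates[cut:]
    if len(post) == 0:
        warnings.warn("post-interruption segment is empty", stacklevel=2)
    return pre, post


def _aicc(res) -> float:
    n = res.nobs
    k = res.params.shape[0]
    if n - k - 1 <= 0:
        return np.inf
    return float(res.aic + 2 * k * (k + 1) / (n - k - 1))


def _fit_one(y: np.ndarray, order, seasonal, s, trend):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", (ConvergenceWarning, ValueWarning,
                                         RuntimeWarning, UserWarning))
        try:
            model = SARIMAX(y, order=order,
                            seasonal_order=(*seasonal, s) if any(seasonal) else (0, 0, 0, 0),
                            trend=trend, enforce_stationarity=True,
                            enforce_invertibility=True)
            res = model.fit(disp=False, maxiter=100)
        except (np.linalg.LinAlgError, ValueError):
            return None
        if not np.isfinite(res.llf):
            return None
        # reject fits whose AR/MA roots sit on the unit circle: they signal
        # root cancellation / boundary overfits with degenerate forecast
        # variances
        for roots in (res.arroots, res.maroots):
            if len(roots) and np.abs(roots).min() < 1.001:
                return None
    return res


def _select_d(y: np.ndarray, max_d: int = MAX_D, alpha: float = 0.05) -> int:
    """KPSS-based differencing order (difference until level-stationary)."""
    d = 0
    z = np.asarray(y, dtype=float)
    while d < max_d:
        if np.allclose(z, z[0]):
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = kpss(z, regression="c", nlags="auto")[1]
        if p >= alpha:
            break
        z = np.diff(z)
        d += 1
    return d


def fit_pre_period(pre: Sequence[float], spec: ArimaSpec = ArimaSpec()) -> tuple[ArimaSpec, object]:
    """Select and fit an ARIMA model on the pre-interruption segment.

    Returns the filled-in :class:`ArimaSpec` and the statsmodels results
    object (needed for forecasting).
    """
    y = np.asarray(pre, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    n = len(y)
    s = spec.seasonal_period

    if spec.selection == "fixed":
        if spec.order is None:
            raise ValueError("fixed selection requires an explicit order")
        trend = spec.trend or ("c" if spec.with_constant else "n")
        res = _fit_one(y, spec.order, spec.seasonal_order, s, trend)
        if res is None:
            raise ArimaFitError(f"fixed model {spec.order} failed to fit")
        return _finalize(spec, spec.order, spec.seasonal_order, trend, res), res

    if n < 30:
        raise ValueError("auto selection requires at least 30 observations")

    d = _select_d(y)
    seasonal_ok = s > 1 and n >= 2 * s + 10
    # With too little data for seasonal identification the seasonal family
    # is skipped entirely (D = P = Q = 0).
    # The deterministic component is structural, not searched: a trending
    # series keeps its linear trend (d=0) or drift (d=1) in the model so
    # the counterfactual extrapolates it; AICc would happily drop a weak
    # drift and flatten the forecast.  d=2 admits no constant (it would
    # imply a quadratic trend).
    trends = ("ct",) if d == 0 else ("c",) if d == 1 else ("n",)
    tried: dict[tuple, float] = {}
    best: tuple | None = None
    best_res = None

    def attempt(p, q, sp, sq, trend):
        nonlocal best, best_res
        if p > MAX_P or q > MAX_Q or p < 0 or q < 0:
            return
        if sp < 0 or sq < 0 or sp > MAX_SP or sq > MAX_SQ:
            return
        if not seasonal_ok and (sp or sq):
            return
        if trend not in trends:
            return
        key = (p, q, sp, sq, trend)
        if key in tried:
            return
        res = _fit_one(y, (p, d, q), (sp, 0, sq), s, trend)
        tried[key] = np.inf if res is None else _aicc(res)
        if res is not None and (best is None or tried[key] < tried[best]):
            best, best_res = key, res

    start_trend = trends[-1] if d < 2 else "n"
    for p, q in [(2, 2), (0, 0), (1, 0), (0, 1)]:
        for trend in {start_trend, "c" if "c" in trends else "n"}:
            attempt(p, q, 1 if seasonal_ok else 0, 1 if seasonal_ok else 0, trend)
            attempt(p, q, 0, 0, trend)
    if best is None:
        raise ArimaFitError(
            f"no starting model converged (tried {sorted(tried)})")

    improved = True
    while improved:
        improved = False
        p, q, sp, sq, trend = best
        neighbours = [
            (p + 1, q, sp, sq, trend), (p - 1, q, sp, sq, trend),
            (p, q + 1, sp, sq, trend), (p, q - 1, sp, sq, trend),
            (p + 1, q + 1, sp, sq, trend), (p - 1, q - 1, sp, sq, trend),
            (p, q, sp + 1, sq, trend), (p, q, sp - 1, sq, trend),
            (p, q, sp, sq + 1, trend), (p, q, sp, sq - 1, trend),
        ] + [(p, q, sp, sq, t) for t in trends if t != trend]
        for cand in neighbours:
            attempt(*cand)
            if best == cand and tried[best] < np.inf:
                improved = True

    p, q, sp, sq, trend = best
    return _finalize(spec, (p, d, q), (sp, 0, sq), trend, best_res), best_res


def _finalize(spec: ArimaSpec, order, seasonal, trend, res) -> ArimaSpec:
    names = list(getattr(res.model, "param_names", None)
                 or [f"p{i}" for i in range(len(res.params))])
    params = {k: float(v) for k, v in zip(names, np.asarray(res.params))}
    ses = {k: float(v) for k, v in zip(names, np.asarray(res.bse))}
    sigma2 = params.get("sigma2", float(np.asarray(res.params)[-1]))
    return ArimaSpec(
        order=tuple(order), seasonal_order=tuple(seasonal),
        seasonal_period=spec.seasonal_period, trend=trend,
        with_constant=trend != "n",
        selection=spec.selection, params=params, param_se=ses,
        sigma2=sigma2, aicc=_aicc(res), n_obs=int(res.nobs))


@dataclass(frozen=True)
class Forecast:
    predicted: np.ndarray
    pi_low: np.ndarray
    pi_high: np.ndarray
    alpha: float


def forecast_counterfactual(res, horizon: int, alpha: float = 0.05,
                            drift_uncertainty: bool = True) -> Forecast:
    """Frozen h-step forecast with normal-theory prediction intervals.

    For a differenced model with a fitted drift the state-space prediction
    variance ignores the drift estimate's own error, which accumulates
    linearly in the horizon and dominates long-horizon intervals; its
    first-order contribution ``(h * se_drift)**2`` is therefore added in
    quadrature.  Reported values are clipped below at zero (a prevalence
    cannot be negative) after the intervals are computed.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    fc = res.get_forecast(steps=horizon)
    mean = np.asarray(fc.predicted_mean, dtype=float)
    se = np.asarray(fc.se_mean, dtype=float)
    if drift_uncertainty:
        names = list(getattr(res.model, "param_names", []))
        d = res.model.order[1] if hasattr(res.model, "order") else 0
        slope_param = ("drift" if "drift" in names          # trend="ct"
                       else "intercept" if d >= 1 and "intercept" in names
                       else None)
        if slope_param is not None:
            se_slope = float(np.asarray(res.bse)[names.index(slope_param)])
            h = np.arange(1, horizon + 1, dtype=float)
            se = np.sqrt(se ** 2 + (h * se_slope) ** 2)
    z = float(_norm.ppf(1 - alpha / 2))
    lo, hi = mean - z * se, mean + z * se
    return Forecast(np.clip(mean, 0, None), np.clip(lo, 0, None),
                    np.clip(hi, 0, None), alpha)


@dataclass(frozen=True)
class CounterfactualResult:
    """Observed vs counterfactual comparison over the post segment."""

    weeks: tuple[int, ...]
    observed: np.ndarray
    predicted: np.ndarray
    pi_low: np.ndarray
    pi_high: np.ndarray
    diff_per_10k: np.ndarray
    odds_ratios: tuple[TwoByTwoResult, ...]
    max_diff_week: int
    first_persistent_week: int | None


def compare(
    observed: Sequence[float],
    forecast: Forecast,
    denominators: Sequence[int],
    first_week: int,
    alpha: float = 0.05,
) -> CounterfactualResult:
    """Per-week observed-minus-predicted differences and odds ratios.

    User counts are reconstructed from the per-10,000 rates and the weekly
    population denominator (half-up rounding), and each week's observed and
    predicted counts are contrasted as a 2x2 table of users vs non-users.
    Also reports the week of maximum absolute difference and the first week
    from which the observed rate exceeds the prediction in every later week.
    """
    obs = np.asarray(observed, dtype=float)
    pred = forecast.predicted
    if len(obs) != len(pred) or len(obs) != len(denominators):
        raise ValueError("observed, predicted and denominators must align")
    diff = obs - pred
    weeks = tuple(range(first_week, first_week + len(obs)))
    ors = []
    for o, p, n in zip(obs, pred, denominators):
        a = int(round_half_up(o * n / PER_10K, 0))
        c = int(round_half_up(p * n / PER_10K, 0))
        ors.append(two_by_two(a, n - a, c, n - c, alpha))
    imax = int(np.argmax(np.abs(diff)))
    above = obs > pred
    first_persistent = None
    for i in range(len(above)):
        if above[i:].all():
            first_persistent = weeks[i]
            break
    return CounterfactualResult(
        weeks, obs, pred, forecast.pi_low, forecast.pi_high, diff,
        tuple(ors), weeks[imax], first_persistent)


_TRANSFORMS = {
    "none": (lambda y: y, lambda y: y),
    "sqrt": (np.sqrt, np.square),
    "log": (np.log, np.exp),
}


def run_its(
    series: PrevalenceSeries,
    spec: ArimaSpec = ArimaSpec(),
    alpha: float = 0.05,
) -> tuple[ArimaSpec, CounterfactualResult]:
    """Split, fit on the (transformed) pre segment, forecast, compare.

    The model is fitted on the variance-stabilized scale given by
    ``spec.transform``; forecasts and interval bounds are mapped back to
    the rate scale through the (monotone) inverse before comparison.
    """
    cal = series.calendar
    pre, post = split_series(series)
    try:
        fwd, inv = _TRANSFORMS[spec.transform]
    except KeyError:
        raise ValueError(f"unknown transform {spec.transform!r}") from None
    if spec.transform == "log" and np.any(pre <= 0):
        raise ValueError("log transform requires strictly positive rates")
    fitted, res = fit_pre_period(fwd(pre), spec)
    fc = forecast_counterfactual(res, len(post), alpha)
    fc = Forecast(inv(fc.predicted), inv(fc.pi_low), inv(fc.pi_high), alpha)
    denoms = series.denominators[cal.interruption_week - 1:]
    result = compare(post, fc, denoms, cal.interruption_week, alpha)
    return fitted, result


RESULT_COLUMNS = ["week", "label_date", "observed", "predicted", "pi_low",
                  "pi_high", "diff_per_10k", "or", "or_low", "or_high"]


def write_result(result: CounterfactualResult, calendar: StudyCalendar,
                 path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for i, week in enumerate(result.weeks):
            orr = result.odds_ratios[i]
            writer.writerow([
                week, label_of_week(week, calendar).isoformat(),
                round_half_up(result.observed[i]), round_half_up(result.predicted[i]),
                round_half_up(result.pi_low[i]), round_half_up(result.pi_high[i]),
                round_half_up(result.diff_per_10k[i]),
                f"{orr.odds_ratio:.2f}", f"{orr.ci_low:.2f}", f"{orr.ci_high:.2f}",
            ])


def write_model_card(fitted: ArimaSpec, path: str | Path) -> None:
    """Key-value text export of the selected model, for auditability."""
    lines = [
        f"selection = {fitted.selection}",
        f"order = {fitted.order}",
        f"seasonal_order = {fitted.seasonal_order} period {fitted.seasonal_period}",
        f"trend = {fitted.trend}",
        f"aicc = {fitted.aicc:.4f}",
        f"sigma2 = {fitted.sigma2:.6g}",
        f"n_obs = {fitted.n_obs}",
    ]
    for name, value in (fitted.params or {}).items():
        se = (fitted.param_se or {}).get(name, float("nan"))
        lines.append(f"coef.{name} = {value:.6g} (se {se:.3g})")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def plot_counterfactual(
    series: PrevalenceSeries,
    result: CounterfactualResult,
    path: str | Path,
) -> None:
    """Observed vs predicted plot with shaded PI, interruption marker and
    dotted burn-in segment."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cal = series.calendar
    weeks = np.arange(1, cal.n_weeks + 1)
    rates = series.rates
    b = cal.burn_in_weeks
    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.plot(weeks[:b + 1], rates[:b + 1], color="black", ls=":", lw=1,
            label=f"burn-in ({b} weeks)")
    ax.plot(weeks[b:], rates[b:], color="black", lw=1.2, label="observed")
    pw = np.asarray(result.weeks)
    ax.plot(pw, result.predicted, color="tab:blue", lw=1.2, label="predicted")
    ax.fill_between(pw, result.pi_low, result.pi_high, color="tab:blue",
                    alpha=0.2, label="95% PI")
    ax.axvline(cal.interruption_week, color="red", lw=1)
    ax.set_xlabel("week of index period")
    ax.set_ylabel(f"users per 10,000 ({series.group}, {series.stratum})")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
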