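"""Growth kinetics: doubling times, half-max times and the Start-candidate filter.

Doubling times are extracted from OD time series either by fitting a
lag-logistic growth model (default; robust to plate-reader noise and to
saturation) or by the classical sliding log-linear window over the
exponential phase.  Relative growth rate follows the time-to-half-max
convention: the reference wild type's half-max time divided by the
culture's, so 1 means wild-type-like and values below 1 mean slower.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
from scipy import optimize, stats

from .datatypes import GrowthCurve, GrowthSummary

__all__ = [
    "estimate_doubling_time",
    "time_to_half_max",
    "relative_growth_rate",
    "summarize_growth",
    "start_candidate_filter",
]


class NoExponentialPhaseError(ValueError):
    """The curve shows no resolvable phase of exponential growth."""


def _lag_logistic(t, od0, od_max, rate, lag):
    """Logistic growth preceded by a flat lag at the inoculum density."""
    tp = np.maximum(t - lag, 0.0)
    return od_max / (1.0 + (od_max / od0 - 1.0) * np.exp(-rate * tp))


def _fit_lag_logistic(t: np.ndarray, od: np.ndarray) -> float:
    """Fit the lag-logistic model; return the exponential rate (per min).

    The carrying-capacity bound is deliberately generous so that curves
    still far from saturation degrade gracefully to a pure exponential
    fit.
    """
    od_top = float(od.max())
    positive = od[od > 0]
    if positive.size == 0 or od_top <= 0:
        raise NoExponentialPhaseError("no exponential phase: no positive OD readings")
    od_start = float(max(positive[0], 1e-6))
    p0 = [od_start, od_top * 1.05, 0.005, 0.0]
    bounds = (
        [1e-9, od_top * 0.5, 1e-9, 0.0],
        [od_top * 2.0, od_top * 1e6, 10.0, float(t[-1]) / 2.0],
    )
    try:
        popt, _ = optimize.curve_fit(
            _lag_logistic, t, od, p0=p0, bounds=bounds, maxfev=50000
        )
    except RuntimeError as exc:  # no convergence
        raise NoExponentialPhaseError(f"no exponential phase: model fit failed ({exc})")
    rate = float(popt[2])
    # reject fits that explain the data no better than a flat line
    resid = od - _lag_logistic(t, *popt)
    if np.var(resid) >= np.var(od):
        raise NoExponentialPhaseError("no exponential phase: growth model does not fit")
    if rate <= 0:
        raise NoExponentialPhaseError("no exponential phase: non-positive growth rate")
    return rate


def _windowed_rate(
    t: np.ndarray, od: np.ndarray, window_points: int, r2_min: float
) -> float:
    """Max slope of log2(OD) over sliding windows with an R^2 floor.

    Among windows whose linear fit reaches ``r2_min`` the steepest is
    taken; if none qualifies, the best-R^2 window with positive slope is
    the fallback.  Returns the slope in log2 units per minute.
    """
    mask = od > 0
    t, od = t[mask], od[mask]
    if t.size < window_points:
        raise NoExponentialPhaseError(
            f"need at least {window_points} positive-OD readings, got {t.size}"
        )
    y = np.log2(od)
    qualifying: list[float] = []
    best_slope, best_r2 = None, -np.inf
    for i in range(t.size - window_points + 1):
        res = stats.linregress(t[i : i + window_points], y[i : i + window_points])
        if res.slope <= 0:
            continue
        r2 = res.rvalue**2
        if r2 >= r2_min:
            qualifying.append(res.slope)
        if r2 > best_r2:
            best_r2, best_slope = r2, res.slope
    if qualifying:
        return max(qualifying)
    if best_slope is None:
        raise NoExponentialPhaseError("no exponential phase: no window with positive slope")
    return best_slope


def estimate_doubling_time(
    curve: GrowthCurve,
    window_points: int = 7,
    r2_min: float = 0.99,
    method: str = "model",
) -> float:
    """Doubling time (min) during the exponential phase.

    Parameters
    ----------
    curve : GrowthCurve
    window_points, r2_min : int, float
        Settings for the sliding-window method.
    method : {"model", "window"}
        "model" (default) fits a lag-logistic growth model and returns
        ln(2)/rate; this is accurate on noisy and saturating curves and
        exact on clean exponentials.  "window" slides a
        ``window_points``-wide log2-linear regression and takes the
        steepest window with fit R^2 >= ``r2_min`` (falling back to the
        best-R^2 window), the classical exponential-phase procedure.

    Raises
    ------
    NoExponentialPhaseError
        If the curve shows no positive growth.
    """
    if method == "model":
        rate = _fit_lag_logistic(curve.times_min, curve.od)
        return float(np.log(2) / rate)
    if method == "window":
        slope = _windowed_rate(curve.times_min, curve.od, window_points, r2_min)
        return float(1.0 / slope)
    raise ValueError(f"unknown method {method!r}")


def time_to_half_max(curve: GrowthCurve) -> float:
    """First time the curve crosses half of its own maximum OD.

    Linear interpolation between the bracketing samples.  A flat curve
    has no half-max crossing and raises.
    """
    od = curve.od
    t = curve.times_min
    od_max, od_min = float(od.max()), float(od.min())
    if od_max <= od_min:
        raise ValueError("flat curve: no half-max crossing")
    half = od_max / 2.0
    if od[0] >= half:
        return float(t[0])
    above = np.nonzero(od >= half)[0]
    i = int(above[0])
    t0, t1 = t[i - 1], t[i]
    y0, y1 = od[i - 1], od[i]
    return float(t0 + (half - y0) / (y1 - y0) * (t1 - t0))


def relative_growth_rate(culture: GrowthCurve, reference_wt_untreated: GrowthCurve) -> float:
    """time_to_half_max(reference) / time_to_half_max(culture).

    1 means the culture grows like the untreated wild-type reference;
    values below 1 mean slower growth (larger = faster).
    """
    return time_to_half_max(reference_wt_untreated) / time_to_half_max(culture)


def summarize_growth(
    curve: GrowthCurve, reference: GrowthCurve | None = None, **dt_kwargs
) -> GrowthSummary:
    """Doubling time, half-max time and (optionally) relative growth rate."""
    rel = relative_growth_rate(curve, reference) if reference is not None else None
    return GrowthSummary(
        doubling_time_min=estimate_doubling_time(curve, **dt_kwargs),
        t_half_min=time_to_half_max(curve),
        relative_growth_rate=rel,
    )


def start_candidate_filter(
    whi_strains: list[str],
    doubling_times: Mapping[str, float],
    wt_map: Mapping[str, str],
    wt_doubling: Mapping[str, float],
    max_increase_pct: float = 10.0,
) -> list[str]:
    """Remove slow-growing Whi mutants from the Start-candidate list.

    A strain is retained when its doubling time does not exceed its
    parental wild type's by more than ``max_increase_pct`` percent; the
    boundary is retained (only strictly *greater* increases are
    removed).  This separates bona fide Start regulators from mutants
    whose small size merely reflects slow growth.
    """
    retained = []
    for strain in whi_strains:
        if strain not in doubling_times:
            raise ValueError(f"no doubling time for strain {strain!r}")
        if strain not in wt_map:
            raise ValueError(f"no wild-type reference for strain {strain!r}")
        wt = wt_map[strain]
        if wt not in wt_doubling:
            raise ValueError(f"no doubling time for wild type {wt!r} (strain {strain!r})")
        if doubling_times[strain] <= (1.0 + max_increase_pct / 100.0) * wt_doubling[wt]:
            retained.append(strain)
    return retained
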