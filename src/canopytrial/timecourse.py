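"""Time-course model fitting and temporal-parameter extraction.

Seasonal trajectories of canopy traits (LAI, canopy coverage, NDVI, plant
height, digital biomass) are fitted per plot with three candidate models —
LOWESS, a 3-parameter logistic, and a quadratic polynomial — scored with
six metrics (MAE, RSS, RMSE, R2, AIC, BIC), and the winning fit is used to
extract temporal parameters: peak value and day, days to 50% and full
canopy coverage, and the day the trait starts to decline.

AIC/BIC use the Gaussian profile likelihood, ``n log(RSS/n) + penalty``,
with the error variance counted as a parameter.  For LOWESS the parameter
count is the effective degrees of freedom (trace of the local-linear
smoother matrix), the standard construction for information criteria of
linear smoothers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

GRID_STEP = 0.1  # days; extracted days are reported to this resolution
MODELS = ("lowess", "logistic", "quadratic")


@dataclass
class TraitSeries:
    """One plot's (day, value) sequence for a single trait."""

    plot_id: str
    trait: str
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.shape != self.values.shape:
            raise ValueError("days and values must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")


@dataclass
class FittedCurve:
    model: str
    grid_days: np.ndarray
    grid_values: np.ndarray
    params: np.ndarray
    mae: float
    rss: float
    rmse: float
    r2: float
    aic: float
    bic: float
    effective_df: float
    converged: bool = True
    data_days: np.ndarray | None = None


@dataclass
class TemporalSummary:
    """Extracted temporal parameters of one plot x trait."""

    plot_id: str
    trait: str
    model_used: str
    peak_value: float
    peak_day: float
    peak_censored: bool
    cc50_day: float | None = None
    cc100_day: float | None = None
    decline_onset_day: float | None = None
    max_value: float | None = None
    notes: dict = field(default_factory=dict)


def _metrics(y: np.ndarray, fitted: np.ndarray, k: float) -> dict:
    n = y.size
    resid = y - fitted
    rss = float(resid @ resid)
    rmse = math.sqrt(rss / n)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -np.inf)
    # Gaussian profile log-likelihood; floor avoids log(0) on exact fits
    ll_term = n * math.log(max(rss, 1e-300) / n)
    return {
        "mae": float(np.mean(np.abs(resid))),
        "rss": rss,
        "rmse": rmse,
        "r2": r2,
        "aic": ll_term + 2.0 * k,
        "bic": ll_term + k * math.log(n),
    }


def _dense_grid(days: np.ndarray) -> np.ndarray:
    n = int(round((days[-1] - days[0]) / GRID_STEP))
    return days[0] + GRID_STEP * np.arange(n + 1)


def _lowess_edf(days: np.ndarray, frac: float) -> float:
    """Trace of the tricube local-linear smoother matrix (non-robust pass)."""
    n = days.size
    r = max(2, int(math.ceil(frac * n)))
    tr = 0.0
    for i in range(n):
        d = np.abs(days - days[i])
        h = np.sort(d)[r - 1]
        if h == 0:
            tr += 1.0
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        x = days - days[i]
        s0, s1, s2 = w.sum(), (w * x).sum(), (w * x * x).sum()
        det = s0 * s2 - s1 * s1
        if det <= 0:
            tr += 1.0
            continue
        # hat_ii = w_i * [1,0] (X'WX)^-1 [1,0]' at x_i = 0
        tr += w[i] * s2 / det
    return float(tr)


def _fit_lowess(days, values, frac: float, it: int) -> FittedCurve:
    sm = _sm_lowess(values, days, frac=frac, it=it, return_sorted=True)
    fitted = sm[:, 1]
    grid = _dense_grid(days)
    spline = CubicSpline(days, fitted, bc_type="natural")
    edf = _lowess_edf(days, frac)
    m = _metrics(values, fitted, k=edf + 1.0)
    return FittedCurve(
        model="lowess", grid_days=grid, grid_values=spline(grid),
        params=np.array([frac, it]), effective_df=edf, data_days=days.copy(), **m,
    )


def _logistic(d, asym, mid, rate):
    return asym / (1.0 + np.exp(-rate * (d - mid)))


def _fit_logistic(days, values) -> FittedCurve:
    vmax = float(np.max(values))
    span = days[-1] - days[0]
    # data-driven start: midpoint at the half-maximum crossing
    half_idx = int(np.argmin(np.abs(values - vmax / 2.0)))
    starts = [
        (vmax, days[half_idx], 4.0 / max(span, 1.0)),
        (vmax * 1.1, days[len(days) // 2], 0.2),
        (vmax * 1.5, days[0] + span / 3.0, 0.1),
        (vmax, days[0] + 2 * span / 3.0, 0.5),
        (max(vmax, 1e-6) * 2.0, days[half_idx], 0.05),
    ]
    lo = [1e-9, days[0] - span, 1e-6]
    hi = [max(vmax, 1e-6) * 10.0 + 1e-6, days[-1] + span, np.inf]
    best, best_rss = None, np.inf
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            popt, _ = curve_fit(
                _logistic, days, values, p0=p0, bounds=(lo, hi), maxfev=5000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(((values - _logistic(days, *popt)) ** 2).sum())
        if rss < best_rss:
            best, best_rss = popt, rss
    grid = _dense_grid(days)
    if best is None:
        return FittedCurve(
            model="logistic", grid_days=grid, grid_values=np.full_like(grid, np.nan),
            params=np.full(3, np.nan), mae=np.inf, rss=np.inf, rmse=np.inf,
            r2=-np.inf, aic=np.inf, bic=np.inf, effective_df=3.0, converged=False,
        )
    # a rate pinned at its lower bound, or a fit no better than a constant,
    # means the data carry no sigmoidal growth signal; report
    # non-convergence rather than a flat pseudo-fit
    fitted = _logistic(days, *best)
    m = _metrics(values, fitted, k=4.0)
    converged = best[2] > 2e-6 and m["r2"] > 0.0
    return FittedCurve(
        model="logistic", grid_days=grid, grid_values=_logistic(grid, *best),
        params=np.asarray(best), effective_df=3.0, converged=converged, **m,
    )


def _fit_quadratic(days, values) -> FittedCurve:
    coeffs = np.polyfit(days, values, 2)
    fitted = np.polyval(coeffs, days)
    grid = _dense_grid(days)
    m = _metrics(values, fitted, k=4.0)
    return FittedCurve(
        model="quadratic", grid_days=grid, grid_values=np.polyval(coeffs, grid),
        params=coeffs, effective_df=3.0, **m,
    )


def fit_models(
    series: TraitSeries, lowess_frac: float = 0.5, lowess_it: int = 2
) -> dict[str, FittedCurve]:
    """Fit LOWESS, logistic and quadratic models to one series.

    Needs at least 4 points (quadratic); the logistic additionally needs 5
    and may legitimately fail to converge (flagged, not raised).
    """
    days, values = series.days, series.values
    if days.size < 4:
        raise ValueError("need >= 4 time points to fit models")
    fits = {
        "lowess": _fit_lowess(days, values, lowess_frac, lowess_it),
        "quadratic": _fit_quadratic(days, values),
    }
    if days.size >= 5:
        fits["logistic"] = _fit_logistic(days, values)
    return fits


def select_model(fits: dict[str, FittedCurve]) -> str:
    """Best converged fit by AIC; ties broken by BIC, then RMSE, then order."""
    ok = [(name, f) for name, f in fits.items() if f.converged]
    if not ok:
        raise ValueError("no model converged")
    order = {m: i for i, m in enumerate(MODELS)}
    return min(ok, key=lambda kv: (kv[1].aic, kv[1].bic, kv[1].rmse, order[kv[0]]))[0]


def extract_peak(fit: FittedCurve) -> tuple[float, float, bool]:
    """(peak_value, peak_day, censored) from the dense-grid maximum.

    ``censored`` marks a maximum at the window boundary (the true peak may
    lie outside the sampled season).
    """
    k = int(np.argmax(fit.grid_values))
    censored = k in (0, fit.grid_values.size - 1)
    return float(fit.grid_values[k]), float(round(fit.grid_days[k], 1)), censored


def extract_threshold_crossing(
    fit: FittedCurve, threshold: float
) -> tuple[float | None, str]:
    """First day the fitted curve reaches ``threshold`` (percent scale).

    Linear interpolation between the bracketing grid points.  Returns
    ``(day, "")`` or ``(None, reason)`` if the curve never reaches it.
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError("threshold must be in (0, 100]")
    v = fit.grid_values
    above = np.nonzero(v >= threshold)[0]
    if above.size == 0:
        return None, "never reached"
    k = int(above[0])
    if k == 0:
        return float(fit.grid_days[0]), ""
    d0, d1 = fit.grid_days[k - 1], fit.grid_days[k]
    v0, v1 = v[k - 1], v[k]
    day = d0 + (threshold - v0) / (v1 - v0) * (d1 - d0) if v1 != v0 else d1
    return float(round(day, 1)), ""


def extract_decline_onset(
    fit: FittedCurve, delta: float = 0.01, min_run: int = 3
) -> tuple[float | None, str]:
    """Day the fitted curve starts its sustained decline from the peak.

    Detection: the first grid day past the peak where the curve has
    dropped below ``(1 - delta) x peak`` and stays below for ``min_run``
    consecutive grid points.  The raw crossing day lags the true onset by
    the time the curve needs to lose ``delta x peak`` (and, for smoothers,
    leads it where the plateau-decline corner is rounded off), so the
    reported day is refined by back-projecting the post-corner decline
    trend line onto the plateau level: a curve that is flat at its peak
    until day *d* and declines linearly afterwards yields *d* exactly,
    whatever the decline rate.  Returns ``(None, reason)`` for curves that
    never decline.
    """
    peak_value, _, _ = extract_peak(fit)
    k_peak = int(np.argmax(fit.grid_values))
    target = (1.0 - delta) * peak_value
    below = fit.grid_values[k_peak:] < target
    if not below.any():
        return None, "no decline observed"
    run = 0
    k_cross = None
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= min_run:
            k_cross = k_peak + i - min_run + 1
            break
    if k_cross is None:
        return None, "decline did not persist"
    cross_day = float(fit.grid_days[k_cross])
    # clearance past the corner: half the smoother window for LOWESS fits
    # (the corner of a kinked curve is rounded over that span), none for
    # parametric fits
    if fit.model == "lowess" and fit.data_days is not None and fit.data_days.size > 1:
        frac = float(fit.params[0])
        spacing = float(np.mean(np.diff(fit.data_days)))
        clearance = 0.5 * math.ceil(frac * fit.data_days.size) * spacing
    else:
        clearance = 0.0
    seg_start = min(cross_day + clearance, fit.grid_days[-1] - 3.0)
    seg = fit.grid_days >= seg_start
    if seg.sum() < 10 or seg_start <= cross_day - GRID_STEP / 2:
        return float(round(cross_day, 1)), ""
    slope, intercept = np.polyfit(fit.grid_days[seg], fit.grid_values[seg], 1)
    if slope >= 0:
        return float(round(cross_day, 1)), ""
    onset = (peak_value - intercept) / slope
    onset = float(np.clip(onset, fit.grid_days[k_peak], fit.grid_days[-1]))
    return float(round(onset, 1)), ""


def summarize_series(
    series: TraitSeries,
    model: str = "auto",
    cc100_threshold: float = 99.5,
    decline_delta: float = 0.01,
    lowess_frac: float = 0.5,
) -> TemporalSummary:
    """Fit, select and extract the temporal parameters of one series.

    Canopy-closure days (CC50/CC100) are extracted for coverage series
    (trait ``CC``, percent scale); decline onset for NDVI; maximum value
    for plant height.  ``model='auto'`` applies the AIC selection rule.
    """
    fits = fit_models(series, lowess_frac=lowess_frac)
    used = select_model(fits) if model == "auto" else model
    if used not in fits:
        raise KeyError(f"model {used!r} not among fitted models {sorted(fits)}")
    fit = fits[used]
    peak_value, peak_day, censored = extract_peak(fit)
    out = TemporalSummary(
        plot_id=series.plot_id, trait=series.trait, model_used=used,
        peak_value=peak_value, peak_day=peak_day, peak_censored=censored,
    )
    if series.trait == "CC":
        out.cc50_day, r50 = extract_threshold_crossing(fit, 50.0)
        out.cc100_day, r100 = extract_threshold_crossing(fit, cc100_threshold)
        out.notes.update({k: v for k, v in (("cc50", r50), ("cc100", r100)) if v})
    if series.trait == "NDVI":
        out.decline_onset_day, rd = extract_decline_onset(fit, delta=decline_delta)
        if rd:
            out.notes["decline"] = rd
    if series.trait == "PH":
        out.max_value = peak_value
    return out


def summarize_table(df: pd.DataFrame, model: str = "auto", **kwargs) -> pd.DataFrame:
    """Summarize every (plot_id, trait) series of a long table."""
    rows = []
    for (pid, trait), grp in df.groupby(["plot_id", "trait"], sort=True):
        grp = grp.sort_values("day")
        s = TraitSeries(plot_id=str(pid), trait=str(trait),
                        days=grp["day"].to_numpy(), values=grp["value"].to_numpy())
        summ = summarize_series(s, model=model, **kwargs)
        rows.append({
            "plot_id": summ.plot_id, "trait": summ.trait,
            "model_used": summ.model_used, "peak_value": summ.peak_value,
            "peak_day": summ.peak_day, "peak_censored": summ.peak_censored,
            "cc50_day": summ.cc50_day, "cc100_day": summ.cc100_day,
            "decline_onset_day": summ.decline_onset_day,
            "max_value": summ.max_value,
        })
    return pd.DataFrame(rows)
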