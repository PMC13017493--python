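"""Peak-LAI / yield relationship and the quadratic yield optimum.

Within each stratum (location x row spacing), grain yield is regressed on
peak leaf area index with a linear and a quadratic model; the models are
compared by AIC, BIC, R2 and RMSE, and — when the quadratic is concave —
the vertex ``-b1 / (2 b2)`` estimates the peak LAI that maximizes yield.

Information criteria use the Gaussian profile likelihood
``n log(RSS/n) + penalty`` with the error variance counted among the
parameters (k = 3 linear, k = 4 quadratic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class LaiYieldFit:
    """One OLS fit of yield on peak LAI (degree 1 or 2)."""

    degree: int
    coefficients: np.ndarray  # ascending order: b0, b1[, b2]
    aic: float
    bic: float
    r2: float
    rmse: float
    rss: float
    n: int
    stratum: str = ""

    def predict(self, x) -> np.ndarray:
        return np.polyval(self.coefficients[::-1], np.asarray(x, dtype=float))


@dataclass
class OptimumEstimate:
    """Vertex of the quadratic fit: the yield-maximizing peak LAI."""

    optimal_lai: float | None
    valid: bool
    reason: str = ""
    extrapolated: bool = False
    stratum: str = ""


def _ols_fit(x: np.ndarray, y: np.ndarray, degree: int, stratum: str) -> LaiYieldFit:
    n = x.size
    coeffs_desc = np.polyfit(x, y, degree)
    fitted = np.polyval(coeffs_desc, x)
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -np.inf)
    k = degree + 2  # coefficients + error variance
    ll = n * math.log(max(rss, 1e-300) / n)
    return LaiYieldFit(
        degree=degree, coefficients=coeffs_desc[::-1].copy(),
        aic=ll + 2 * k, bic=ll + k * math.log(n),
        r2=r2, rmse=math.sqrt(rss / n), rss=rss, n=n, stratum=stratum,
    )


def fit_lai_yield(
    peak_lai, yield_values, stratum: str = ""
) -> tuple[LaiYieldFit, LaiYieldFit]:
    """(linear, quadratic) OLS fits of yield on peak LAI."""
    x = np.asarray(peak_lai, dtype=float)
    y = np.asarray(yield_values, dtype=float)
    if x.size != y.size:
        raise ValueError("peak_lai and yield_values must have equal length")
    if x.size < 4:
        raise ValueError("need >= 4 observations to compare linear vs quadratic")
    if np.ptp(x) == 0:
        raise ValueError("constant peak LAI: design matrix is singular")
    return _ols_fit(x, y, 1, stratum), _ols_fit(x, y, 2, stratum)


def optimal_lai(
    quadratic: LaiYieldFit, lai_range: tuple[float, float] | None = None
) -> OptimumEstimate:
    """Vertex of a concave quadratic fit; invalid without curvature (b2 >= 0)."""
    if quadratic.degree != 2:
        raise ValueError("optimal_lai needs the quadratic fit")
    b0, b1, b2 = quadratic.coefficients
    if b2 == 0:
        return OptimumEstimate(None, False, reason="no curvature",
                               stratum=quadratic.stratum)
    if b2 > 0:
        return OptimumEstimate(None, False, reason="convex fit (minimum, not maximum)",
                               stratum=quadratic.stratum)
    vertex = -b1 / (2.0 * b2)
    extrapolated = bool(
        lai_range is not None and not (lai_range[0] <= vertex <= lai_range[1])
    )
    return OptimumEstimate(float(vertex), True, extrapolated=extrapolated,
                           stratum=quadratic.stratum)


def compare_models(linear: LaiYieldFit, quadratic: LaiYieldFit) -> dict:
    """Per-metric winner and overall AIC pick (parsimony breaks AIC ties)."""
    winners = {}
    for metric, better_low in (("aic", True), ("bic", True),
                               ("rmse", True), ("r2", False)):
        lv, qv = getattr(linear, metric), getattr(quadratic, metric)
        if lv == qv:
            winners[metric] = "linear"  # fewer parameters
        elif (qv < lv) == better_low:
            winners[metric] = "quadratic"
        else:
            winners[metric] = "linear"
    return {
        "stratum": linear.stratum,
        "winners": winners,
        "selected": winners["aic"],
        "linear": {m: getattr(linear, m) for m in ("aic", "bic", "r2", "rmse")},
        "quadratic": {m: getattr(quadratic, m) for m in ("aic", "bic", "r2", "rmse")},
    }


def optimum_by_stratum(df, lai_col="peak_lai", yield_col="yield",
                       stratum_col="stratum") -> list[dict]:
    """Run the model comparison and vertex estimate independently per stratum."""
    out = []
    for key, grp in df.groupby(stratum_col, sort=True):
        x = grp[lai_col].to_numpy(dtype=float)
        y = grp[yield_col].to_numpy(dtype=float)
        lin, quad = fit_lai_yield(x, y, stratum=str(key))
        est = optimal_lai(quad, lai_range=(float(x.min()), float(x.max())))
        rec = compare_models(lin, quad)
        rec.update({
            "optimal_lai": est.optimal_lai, "optimum_valid": est.valid,
            "optimum_extrapolated": est.extrapolated, "optimum_reason": est.reason,
            "n": int(len(grp)),
        })
        out.append(rec)
    return out
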