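"""FvCB C3 photosynthesis model and A-Ci curve fitting.

Implements the Farquhar–von Caemmerer–Berry model with Rubisco-limited and
RuBP-regeneration-limited rates,

    Wc = Vcmax (Ci - Gamma*) / (Ci + Kc (1 + O/Ko))
    Wj = J (Ci - Gamma*) / (4 Ci + 8 Gamma*)
    A  = min(Wc, Wj) - Rd,

fits (Vcmax, J, Rd) to measured A-Ci curves by derivative-free
least-squares with multi-start, and normalizes the estimates to 25 degC
with Arrhenius temperature responses.  Mesophyll conductance is treated as
infinite, so Ci is the substrate concentration and the fitted parameters
are apparent (Ci-based) values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from canopytrial import _bernacchi as _b

#: Measurement protocol: reference CO2 setpoints (ppm) in measurement order.
#: 400 ppm appears three times (initial, and twice on return before the
#: high-CO2 ramp); repeats are retained as independent observations.
PROTOCOL_CI_SETPOINTS = (
    400.0, 300.0, 200.0, 100.0, 75.0, 50.0, 25.0,
    400.0, 400.0, 600.0, 800.0, 1000.0, 1200.0, 1800.0,
)


def arrhenius_factor(ha: float, tleaf_c: float) -> float:
    """Arrhenius scaling factor at ``tleaf_c`` relative to 25 degC.

    ``f = exp(Ha/R * (1/298.15 - 1/T_K))``; equals 1 at 25 degC.
    """
    tk = tleaf_c + 273.15
    return math.exp(ha / _b.R_KJ * (1.0 / _b.T25_K - 1.0 / tk))


@dataclass(frozen=True)
class Kinetics:
    """Rubisco kinetics and their temperature responses.

    Concentrations in umol mol-1 except ``ko`` and ``o`` (mmol mol-1).
    ``*_ha`` are activation energies (kJ mol-1) of the Arrhenius response.
    """

    gamma_star25: float = _b.GAMMA_STAR_25
    kc25: float = _b.KC_25
    ko25: float = _b.KO_25
    o: float = _b.OXYGEN_MMOL
    gamma_star_ha: float = _b.GAMMA_STAR_HA
    kc_ha: float = _b.KC_HA
    ko_ha: float = _b.KO_HA
    vcmax_ha: float = _b.VCMAX_HA
    j_ha: float = _b.J_HA
    rd_ha: float = _b.RD_HA

    def __post_init__(self) -> None:
        for name in ("gamma_star25", "kc25", "ko25", "o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"kinetic constant {name!r} must be positive")

    def at(self, tleaf_c: float) -> tuple[float, float, float]:
        """(gamma_star, kc, ko) at leaf temperature ``tleaf_c`` (degC)."""
        return (
            self.gamma_star25 * arrhenius_factor(self.gamma_star_ha, tleaf_c),
            self.kc25 * arrhenius_factor(self.kc_ha, tleaf_c),
            self.ko25 * arrhenius_factor(self.ko_ha, tleaf_c),
        )


BERNACCHI = Kinetics()

# response-coefficient lookup for normalize_25
_PARAM_HA = {"vcmax": _b.VCMAX_HA, "j": _b.J_HA, "jmax": _b.J_HA, "rd": _b.RD_HA}


@dataclass
class ACiCurve:
    """One leaf's A-Ci response: Ci (umol mol-1), A (umol m-2 s-1), Tleaf (degC)."""

    ci: np.ndarray
    a: np.ndarray
    tleaf: np.ndarray
    curve_id: str = "curve"

    def __post_init__(self) -> None:
        self.ci = np.asarray(self.ci, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.tleaf = np.broadcast_to(
            np.asarray(self.tleaf, dtype=float), self.ci.shape
        ).copy()
        if self.ci.shape != self.a.shape:
            raise ValueError("ci and a must have equal length")
        if np.any(self.ci <= 0):
            raise ValueError("all Ci values must be positive")

    def __len__(self) -> int:
        return self.ci.size


@dataclass
class ACiFit:
    """Fitted FvCB parameters, normalized to 25 degC."""

    vcmax25: float
    jmax25: float
    rd25: float
    rss: float
    converged: bool
    limiting: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    tleaf: float = 25.0


def fvcb_forward(
    ci, vcmax: float, j: float, rd: float,
    kinetics: Kinetics = BERNACCHI, tleaf_c: float = 25.0,
):
    """Predicted net assimilation A and per-point limiting process.

    Parameters are at leaf temperature; kinetics are evaluated at
    ``tleaf_c``.  Returns ``(a, limiting)`` where ``limiting`` is
    ``"rubisco"`` where Wc < Wj and ``"rubp"`` otherwise.
    """
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= 0):
        raise ValueError("Ci must be positive")
    gamma_star, kc, ko = kinetics.at(tleaf_c)
    wc = vcmax * (ci - gamma_star) / (ci + kc * (1.0 + kinetics.o / ko))
    wj = j * (ci - gamma_star) / (4.0 * ci + 8.0 * gamma_star)
    a = np.minimum(wc, wj) - rd
    limiting = np.where(wc < wj, "rubisco", "rubp")
    return a, limiting


def normalize_25(value: float, tleaf_c: float, param: str) -> float:
    """Scale a parameter estimated at ``tleaf_c`` to its 25 degC value.

    Divides by the Arrhenius factor of the parameter's temperature
    response; identity at 25 degC.  ``param`` is one of ``vcmax``, ``j``
    (alias ``jmax``) or ``rd``.
    """
    key = param.lower()
    if key not in _PARAM_HA:
        raise KeyError(f"no temperature-response coefficients for {param!r}")
    return value / arrhenius_factor(_PARAM_HA[key], tleaf_c)


def _multistart_points(rng: np.random.Generator, n_extra: int):
    """Coarse-grid corners plus seeded jitter starts over the plausible box."""
    base = [
        (50.0, 100.0, 1.0),
        (120.0, 200.0, 1.5),
        (200.0, 350.0, 2.0),
        (30.0, 60.0, 0.5),
        (90.0, 300.0, 3.0),
    ]
    lo = np.array([20.0, 40.0, 0.1])
    hi = np.array([250.0, 400.0, 5.0])
    for _ in range(n_extra):
        base.append(tuple(rng.uniform(lo, hi)))
    return base


def fit_aci(
    curve: ACiCurve,
    kinetics: Kinetics = BERNACCHI,
    n_starts: int = 5,
    seed: int | None = 0,
    xatol: float = 1e-8,
) -> ACiFit:
    """Estimate (Vcmax, J, Rd) by RSS minimization over the whole curve.

    Under a Gaussian error model, minimizing the residual sum of squares
    is maximum-likelihood estimation.  Nelder-Mead simplex search from
    multiple starting points; the best optimum is kept.  Estimates are
    made at the curve's mean leaf temperature and then normalized to
    25 degC.  Non-convergence from every start is reported via
    ``converged=False`` with the best parameters found, not raised.
    """
    if np.unique(curve.ci).size < 5:
        raise ValueError("A-Ci fitting needs at least 5 distinct Ci points")
    tleaf = float(np.mean(curve.tleaf))
    a_obs = curve.a

    def rss(theta):
        v, j, rd = theta
        if v <= 0 or j <= 0 or rd < 0:
            return 1e12
        pred, _ = fvcb_forward(curve.ci, v, j, rd, kinetics, tleaf)
        r = pred - a_obs
        return float(r @ r)

    rng = np.random.default_rng(seed)
    best = None
    any_ok = False
    for x0 in _multistart_points(rng, max(0, n_starts - 5)):
        res = minimize(
            rss, x0, method="Nelder-Mead",
            options={"xatol": xatol, "fatol": xatol, "maxiter": 5000, "maxfev": 8000},
        )
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    v, j, rd = best.x
    pred, limiting = fvcb_forward(curve.ci, v, j, rd, kinetics, tleaf)
    return ACiFit(
        vcmax25=normalize_25(v, tleaf, "vcmax"),
        jmax25=normalize_25(j, tleaf, "j"),
        rd25=normalize_25(rd, tleaf, "rd"),
        rss=float(best.fun),
        converged=any_ok,
        limiting=limiting,
        tleaf=tleaf,
    )


def fit_aci_table(df, kinetics: Kinetics = BERNACCHI, seed: int | None = 0):
    """Fit every curve in a long table (curve_id, ci, a, tleaf) -> tidy results."""
    import pandas as pd

    rows = []
    for cid, grp in df.groupby("curve_id", sort=True):
        curve = ACiCurve(
            ci=grp["ci"].to_numpy(), a=grp["a"].to_numpy(),
            tleaf=grp["tleaf"].to_numpy(), curve_id=str(cid),
        )
        fit = fit_aci(curve, kinetics=kinetics, seed=seed)
        rows.append(
            {"curve_id": cid, "vcmax25": fit.vcmax25, "jmax25": fit.jmax25,
             "rd25": fit.rd25, "rss": fit.rss, "converged": fit.converged}
        )
    return pd.DataFrame(rows)
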