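"""Synthetic-trial generators with stored ground truth.

Emulates the data-generating structure of an unreplicated soybean
near-isogenic-line trial laid out as a Type-II Modified Augmented Design
(MAD): blocks of 25 plots on a 5x5 grid with the replicated primary check
(the recurrent parent) at each block centre and the two donor-parent
secondary checks placed once per block at random non-central cells.
Downstream stages (spatial adjustment, time-course extraction, image
indices, voxel biomass, A-Ci fitting, the yield-LAI optimum) can therefore
be verified against exact truth.

Every generator is deterministic for a fixed ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from canopytrial import aci as _aci

ROLES = ("test", "check1", "check2a", "check2b")

#: parental genotype ids carried by the check plots
CHECK_GENOTYPES = {
    "check1": "recurrent_parent",
    "check2a": "donor_parent_1",
    "check2b": "donor_parent_2",
}


@dataclass(frozen=True)
class PlotRecord:
    """One plot of the field grid (0-based global and block-grid addresses)."""

    block_id: int
    block_row: int
    block_col: int
    row_index: int
    column_index: int
    role: str
    genotype_id: str
    leaf_shape: str  # "broad" | "narrow"


@dataclass
class FieldLayout:
    """A MAD field: blocks tiled row-wise on a (block_grid_rows x block_grid_cols) grid."""

    plots: list[PlotRecord]
    n_blocks: int
    block_rows: int
    block_cols: int
    block_grid: tuple[int, int]
    location_label: str = "SF"
    spacing_label: str = "76cm"

    @property
    def plots_per_block(self) -> int:
        return self.block_rows * self.block_cols

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(p) for p in self.plots])
        df.insert(0, "plot_id", [
            f"{self.location_label}_{self.spacing_label}_b{p.block_id:02d}"
            f"_r{p.row_index:02d}c{p.column_index:02d}"
            for p in self.plots
        ])
        df["location"] = self.location_label
        df["spacing"] = self.spacing_label
        return df


def generate_layout(
    n_blocks: int,
    block_shape: tuple[int, int] = (5, 5),
    seed: int = 0,
    n_test_genotypes: int | None = None,
    location_label: str = "SF",
    spacing_label: str = "76cm",
    block_grid: tuple[int, int] | None = None,
) -> FieldLayout:
    """Lay out a Type-II MAD field.

    Each block is a ``block_shape`` grid (odd x odd, so the centre cell is
    unique) holding one primary check at the centre and each secondary
    check exactly once at a uniformly random non-central cell.  Blocks tile
    row-wise into a near-square block grid unless ``block_grid`` is given.
    Test plots carry unique genotype ids unless ``n_test_genotypes``
    requests replication (ids then assigned uniformly at random).
    """
    br, bc = block_shape
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if br % 2 == 0 or bc % 2 == 0:
        raise ValueError(
            f"block_shape {block_shape} has an even dimension: no unique centre cell"
        )
    if block_grid is None:
        bg_cols = math.ceil(math.sqrt(n_blocks))
        bg_rows = math.ceil(n_blocks / bg_cols)
    else:
        bg_rows, bg_cols = block_grid
        if bg_rows * bg_cols < n_blocks:
            raise ValueError("block_grid too small for n_blocks")

    rng = np.random.default_rng(seed)
    centre = (br // 2, bc // 2)
    n_test_plots = n_blocks * (br * bc - 3)
    if n_test_genotypes is None:
        test_ids = [f"g{i:04d}" for i in range(n_test_plots)]
    else:
        if n_test_genotypes < 1:
            raise ValueError("n_test_genotypes must be >= 1")
        pool = [f"g{i:04d}" for i in range(n_test_genotypes)]
        test_ids = [pool[k] for k in rng.integers(0, n_test_genotypes, n_test_plots)]
    # half the test genotypes are broad, half narrow (near-isogenic pairs)
    uniq = sorted(set(test_ids))
    shape_of = {g: ("broad" if i % 2 == 0 else "narrow") for i, g in enumerate(uniq)}
    shape_of.update({"recurrent_parent": "broad",
                     "donor_parent_1": "narrow", "donor_parent_2": "narrow"})

    plots: list[PlotRecord] = []
    t = 0
    for b in range(n_blocks):
        g_row, g_col = divmod(b, bg_cols)
        cells = [(r, c) for r in range(br) for c in range(bc) if (r, c) != centre]
        sec_idx = rng.choice(len(cells), size=2, replace=False)
        sec = {cells[sec_idx[0]]: "check2a", cells[sec_idx[1]]: "check2b"}
        for r in range(br):
            for c in range(bc):
                if (r, c) == centre:
                    role = "check1"
                elif (r, c) in sec:
                    role = sec[(r, c)]
                else:
                    role = "test"
                if role == "test":
                    gid = test_ids[t]
                    t += 1
                else:
                    gid = CHECK_GENOTYPES[role]
                plots.append(PlotRecord(
                    block_id=b, block_row=g_row, block_col=g_col,
                    row_index=g_row * br + r, column_index=g_col * bc + c,
                    role=role, genotype_id=gid, leaf_shape=shape_of[gid],
                ))
    return FieldLayout(
        plots=plots, n_blocks=n_blocks, block_rows=br, block_cols=bc,
        block_grid=(bg_rows, bg_cols),
        location_label=location_label, spacing_label=spacing_label,
    )


@dataclass
class TrialTruth:
    """Ground truth of a simulated trial.

    ``value = grand_mean + genotype_effects[g] + r_i + c_j [+ trend] + eps``
    with ``eps ~ Normal(0, noise_sd)``.  Row/column effects are additive
    spatial offsets stored as deviations summing to zero; with
    ``effect_scale='block'`` (default) they are indexed by block-grid row
    and column — the resolution the design's centred checks can estimate —
    and with ``'plot'`` by global plot row/column.  ``trend`` is an
    optional smooth surface ``f(row_frac, col_frac) -> offset`` for
    robustness studies.
    """

    genotype_effects: dict[str, float]
    row_effects: np.ndarray
    col_effects: np.ndarray
    grand_mean: float = 0.0
    noise_sd: float = 0.0
    effect_scale: str = "block"
    trend: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.row_effects = np.asarray(self.row_effects, dtype=float)
        self.col_effects = np.asarray(self.col_effects, dtype=float)
        for name, eff in (("row_effects", self.row_effects),
                          ("col_effects", self.col_effects)):
            scale = max(1.0, float(np.max(np.abs(eff))) if eff.size else 1.0)
            if eff.size and abs(eff.sum()) > 1e-8 * scale:
                raise ValueError(f"{name} must be deviations summing to 0")
        if self.effect_scale not in ("block", "plot"):
            raise ValueError("effect_scale must be 'block' or 'plot'")


def simulate_trial(layout: FieldLayout, truth: TrialTruth, seed: int = 0) -> pd.DataFrame:
    """Draw one trait realization for every plot of ``layout``.

    Returns the layout joined with a ``value`` column.  With
    ``noise_sd=0`` values are exact (genotype effect plus spatial offsets).
    """
    df = layout.to_frame()
    missing = set(df["genotype_id"]) - set(truth.genotype_effects)
    if missing:
        raise KeyError(
            "no genotype effect for: " + ", ".join(sorted(missing)[:5])
        )
    rng = np.random.default_rng(seed)
    if truth.effect_scale == "block":
        ri = truth.row_effects[df["block_row"].to_numpy()]
        cj = truth.col_effects[df["block_col"].to_numpy()]
    else:
        ri = truth.row_effects[df["row_index"].to_numpy()]
        cj = truth.col_effects[df["column_index"].to_numpy()]
    g = df["genotype_id"].map(truth.genotype_effects).to_numpy(dtype=float)
    value = truth.grand_mean + g + ri + cj
    if truth.trend is not None:
        n_rows = layout.block_grid[0] * layout.block_rows
        n_cols = layout.block_grid[1] * layout.block_cols
        value = value + truth.trend(
            df["row_index"].to_numpy() / max(1, n_rows - 1),
            df["column_index"].to_numpy() / max(1, n_cols - 1),
        )
    if truth.noise_sd > 0:
        value = value + rng.normal(0.0, truth.noise_sd, size=len(df))
    out = df.copy()
    out["value"] = value
    return out


# ---------------------------------------------------------------------------
# time courses


@dataclass
class CurveParams:
    """Ground-truth parameters of one trait time course.

    ``family`` selects the shape: ``logistic`` (sigmoid to ``asymptote``
    with midpoint ``midpoint_day`` and slope ``rate``), ``quadratic``
    (concave parabola peaking at ``asymptote`` on day ``midpoint_day``
    with curvature ``rate``), or ``rise_plateau_decline`` (logistic rise,
    plateau, then linear decline of ``decline_rate`` trait-units/day
    starting at ``decline_onset_day``).
    """

    family: str = "logistic"
    asymptote: float = 100.0
    midpoint_day: float = 38.0
    rate: float = 0.2
    decline_onset_day: float | None = None
    decline_rate: float = 0.0
    noise_sd: float = 0.0
    trait: str = "CC"

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "quadratic", "rise_plateau_decline"):
            raise ValueError(f"unknown curve family {self.family!r}")
        if self.asymptote <= 0:
            raise ValueError("asymptote must be positive")

    def evaluate(self, days) -> np.ndarray:
        d = np.asarray(days, dtype=float)
        if self.family == "logistic":
            return self.asymptote / (1.0 + np.exp(-self.rate * (d - self.midpoint_day)))
        if self.family == "quadratic":
            return self.asymptote - self.rate * (d - self.midpoint_day) ** 2
        onset = self.decline_onset_day
        if onset is None:
            raise ValueError("rise_plateau_decline needs decline_onset_day")
        rise = self.asymptote / (1.0 + np.exp(-self.rate * (np.minimum(d, onset) - self.midpoint_day)))
        return rise - self.decline_rate * np.clip(d - onset, 0.0, None)

    def true_summary(self, day_lo: float, day_hi: float) -> dict:
        """Exact peak / 50%-crossing / decline-onset over [day_lo, day_hi]."""
        grid = np.arange(day_lo, day_hi + 1e-9, 0.01)
        v = self.evaluate(grid)
        k = int(np.argmax(v))
        out = {"peak_value": float(v[k]), "peak_day": float(grid[k]),
               "cc50_day": None, "decline_onset_day": None}
        if self.family in ("logistic", "rise_plateau_decline"):
            out["cc50_day"] = float(self.midpoint_day)
        if self.family == "rise_plateau_decline":
            out["decline_onset_day"] = float(self.decline_onset_day)
        return out


def simulate_timecourse(
    layout: FieldLayout,
    params: CurveParams,
    sampling_days: Sequence[float],
    seed: int = 0,
    asymptote_by_genotype: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-plot time courses of one trait plus the exact truth summary.

    Returns a long table (plot_id, genotype_id, trait, day, value) and the
    ground-truth temporal summary of the noiseless curve.  Per-genotype
    asymptotes (``asymptote_by_genotype``) scale the shared curve so that
    genotypes differ in peak value but not timing.
    """
    days = np.asarray(sampling_days, dtype=float)
    if days.size == 0:
        raise ValueError("sampling_days is empty")
    if np.any(np.diff(days) <= 0):
        raise ValueError("sampling_days must be strictly increasing")
    rng = np.random.default_rng(seed)
    base = params.evaluate(days)
    frames = []
    df = layout.to_frame()
    for pid, gid in zip(df["plot_id"], df["genotype_id"]):
        scale = 1.0
        if asymptote_by_genotype is not None:
            scale = asymptote_by_genotype.get(gid, params.asymptote) / params.asymptote
        vals = base * scale
        if params.noise_sd > 0:
            vals = vals + rng.normal(0.0, params.noise_sd, size=days.size)
        frames.append(pd.DataFrame({
            "plot_id": pid, "genotype_id": gid, "trait": params.trait,
            "day": days, "value": vals,
        }))
    truth = params.true_summary(days[0], days[-1])
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# images and point clouds


def simulate_plot_image(
    coverage_fraction: float,
    shape: tuple[int, int] = (100, 100),
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A two-class (vegetation/soil) 4-channel plot image with truth mask.

    Channels are (R, G, B, NIR) in [0, 1].  Vegetation pixels are built
    with strictly positive Excess Green (2G - R - B) and high NIR; soil
    pixels with non-positive ExG and NIR tracking R.  The vegetation pixel
    count is exactly ``round(coverage_fraction * H * W)``.  ``noise_sd``
    adds clipped Gaussian channel noise (may blur the class margin).
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("image shape must be positive")
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = h * w
    n_veg = int(round(coverage_fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=n_veg, replace=False)] = True

    img = np.empty((n, 4), dtype=float)
    # soil: R >= G slightly, NIR barely above R -> ExG < 0 with a margin
    # (keeps the soil/vegetation ExG clusters separable to histogram
    # precision), NDVI small
    r = rng.uniform(0.25, 0.45, n)
    b = rng.uniform(0.15, 0.35, n)
    g = (r + b) / 2.0 - rng.uniform(0.02, 0.10, n)
    img[:, 0], img[:, 1], img[:, 2] = r, g, b
    img[:, 3] = r * rng.uniform(1.0, 1.2, n)
    # vegetation: G dominant, NIR high -> ExG > 0, NDVI large
    rv = rng.uniform(0.05, 0.20, n_veg)
    bv = rng.uniform(0.05, 0.20, n_veg)
    gv = (rv + bv) / 2.0 + rng.uniform(0.15, 0.35, n_veg)
    img[mask, 0], img[mask, 1], img[mask, 2] = rv, gv, bv
    img[mask, 3] = rng.uniform(0.6, 0.9, n_veg)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return img.reshape(h, w, 4), mask.reshape(h, w)


@dataclass
class PointCloud:
    """Canopy points (x, y, z in metres) over a plot of ``footprint_area`` m2."""

    points: np.ndarray
    footprint_area: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.footprint_area <= 0:
            raise ValueError("footprint area must be positive")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")


def simulate_point_cloud(
    footprint_m: tuple[float, float] = (2.0, 1.0),
    height_m: float = 0.5,
    points_per_m3: float = 1e4,
    seed: int = 0,
) -> PointCloud:
    """Uniform points in an axis-aligned box canopy of the given dimensions."""
    fx, fy = footprint_m
    if fx <= 0 or fy <= 0 or height_m < 0:
        raise ValueError("footprint dimensions must be positive, height non-negative")
    if points_per_m3 <= 0:
        raise ValueError("point density must be positive")
    volume = fx * fy * height_m
    n = int(round(points_per_m3 * volume))
    rng = np.random.default_rng(seed)
    pts = rng.uniform([0, 0, 0], [fx, fy, max(height_m, np.finfo(float).tiny)], (n, 3))
    return PointCloud(points=pts, footprint_area=fx * fy)


def box_lattice_cloud(
    footprint_m: tuple[float, float], height_m: float, step_m: float
) -> PointCloud:
    """Deterministic lattice filling the box, boundaries included.

    Used for voxel-convergence studies where every voxel intersecting the
    box must contain a point.
    """
    fx, fy = footprint_m
    xs = np.arange(0.0, fx + step_m / 2, step_m)
    ys = np.arange(0.0, fy + step_m / 2, step_m)
    zs = np.arange(0.0, height_m + step_m / 2, step_m)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    return PointCloud(points=grid, footprint_area=fx * fy)


# ---------------------------------------------------------------------------
# gas exchange and leaf morphology


def simulate_aci_curve(
    vcmax25: float,
    j25: float,
    rd25: float,
    kinetics: _aci.Kinetics = _aci.BERNACCHI,
    ci_setpoints: Sequence[float] = _aci.PROTOCOL_CI_SETPOINTS,
    noise_sd: float = 0.0,
    seed: int = 0,
    tleaf_c: float = 25.0,
    curve_id: str = "curve",
) -> _aci.ACiCurve:
    """An FvCB-generated A-Ci curve at the measurement protocol's setpoints.

    Parameters are given at 25 degC and scaled to ``tleaf_c`` with the
    stored Arrhenius responses before evaluating the forward model, so a
    round trip through :func:`canopytrial.aci.fit_aci` recovers the
    25 degC inputs.
    """
    if min(vcmax25, j25, rd25) <= 0:
        raise ValueError("FvCB parameters must be positive")
    ci = np.asarray(ci_setpoints, dtype=float)
    if np.any(ci <= 0):
        raise ValueError("all Ci setpoints must be positive")
    v = vcmax25 * _aci.arrhenius_factor(kinetics.vcmax_ha, tleaf_c)
    j = j25 * _aci.arrhenius_factor(kinetics.j_ha, tleaf_c)
    rd = rd25 * _aci.arrhenius_factor(kinetics.rd_ha, tleaf_c)
    a, _ = _aci.fvcb_forward(ci, v, j, rd, kinetics, tleaf_c)
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, ci.size)
    return _aci.ACiCurve(ci=ci, a=a, tleaf=np.full(ci.size, tleaf_c), curve_id=curve_id)


def simulate_leaf_ratios(
    n: int,
    seed: int = 0,
    means: tuple[float, float] = (1.3, 2.4),
    sds: tuple[float, float] = (0.12, 0.25),
    weight_broad: float = 0.5,
) -> pd.DataFrame:
    """Bimodal leaflet length:width ratios for a broad/narrow NIL population.

    Broad-leaf lines centre near 1.3 and narrow-leaf lines near 2.4; the
    population is an equal mixture by default.
    """
    rng = np.random.default_rng(seed)
    broad = rng.random(n) < weight_broad
    vals = np.where(
        broad,
        rng.normal(means[0], sds[0], n),
        rng.normal(means[1], sds[1], n),
    )
    return pd.DataFrame({
        "leaf_ratio": vals,
        "leaf_shape": np.where(broad, "broad", "narrow"),
    })
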