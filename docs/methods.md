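# Methods

This note documents the models, estimators, numerical choices and known
limitations of `canopytrial`, and the conditions under which its
Monte-Carlo validation studies are run.

## Design model and spatial adjustment

A Type-II MAD field consists of `n` blocks, each a 5×5 grid of plots (any
odd×odd shape is supported) with the replicated primary check at the block
centre and each of two secondary checks placed once per block at a
uniformly random non-central cell. Blocks tile row-wise into a near-square
*block grid*; plots carry both global (row, column) and block-grid
addresses.

**Method I** estimates additive row and column effects from the primary
checks and corrects every plot by `Y − R_i − C_j + 2μ`. Because the design
places exactly one centred check per block, the finest resolution at which
the checks can estimate row/column structure is the block grid, so `R_i`
is the mean primary-check value over block row `i` (likewise `C_j` over
block columns), and every plot inherits its block's effects. Block rows or
columns without a check (possible only in degenerate layouts) fall back to
the grand check mean, i.e. a zero estimated deviation. Consequences worth
stating: a spatially flat field is left unchanged; on a noiseless trial
with additive block-scale gradients the adjustment is exact (all
replicates of a genotype collapse to `g + mean(r) + mean(c)`); on a single
row of blocks the method reduces to column centering. Gradients that vary
*within* blocks (e.g. smooth polynomial trends) are only removed at block
resolution — the generator offers such trends precisely to probe this
limit.

**Method III** regresses the per-block primary-check value on the
per-block secondary-check average by OLS and corrects plots by
`Y − β(check1_b − check2_ref) + α`. The reference `check2_ref` defaults to
the across-block mean of the secondary-check averages; a per-block variant
(each block its own reference) is available behind a flag. The formula is
applied as printed, including the additive intercept `α`. The regression
needs ≥ 3 blocks and variance in the secondary-check averages; a
degenerate trial signals "Method III unavailable" and the selection falls
back to Method I alone.

**IWP error.** The printed divisor `2(n₁ + n₂ − 2)` fixes the pooled-
variance reading of "sums of squared differences": `SS_k` is the sum of
squared deviations of secondary check `k`'s per-block values about that
check's own mean. Both secondary checks must appear in ≥ 2 blocks.

**Selection.** `RE = 100 · IWP_original / IWP_adjusted`; the three-rule
decision (none / the method with RE ≥ 100 / the higher of two) is applied
independently per trait and per location × spacing stratum. Ties at
RE ≥ 100 go to Method I, which uses the design structure of every block
rather than a 1-point-per-block regression. Two conventions for degenerate
errors: both IWP errors zero → RE = 100 (no information, no adjustment
preferred); adjusted error exactly zero with a positive original → RE
reported as +∞ with a warning.

## Time-course fitting and extraction

Three candidate models per plot × trait series: LOWESS (statsmodels,
tricube local-linear, robustifying iterations 2, span 0.5 by default), a
3-parameter logistic `A/(1 + e^{−k(t−t₀)})` fitted by bounded nonlinear
least squares from five data-driven starts, and an OLS quadratic. A
logistic whose rate pins at its positive lower bound or whose fit explains
no variance (R² ≤ 0) is reported as failed to converge — growth data that
are not sigmoidal should say so rather than return a flat pseudo-fit.

Fit metrics are MAE, RSS, RMSE, R², and Gaussian-profile information
criteria `n log(RSS/n) + penalty` with the error variance counted as a
parameter: `k = 4` for logistic and quadratic, `k = edf + 1` for LOWESS,
where the effective degrees of freedom are the trace of the tricube
local-linear smoother matrix (computed from the non-robust weight pass;
statsmodels does not expose the hat matrix). Selection: lowest AIC among
converged fits, ties broken by BIC, then RMSE.

Extraction happens on a dense 0.1-day grid (LOWESS fitted values are
carried to the grid by a natural cubic spline through the fitted points;
parametric fits are evaluated directly). Peak = grid argmax, flagged
"censored" at a window boundary. Threshold crossings (CC50 at 50%, CC100
at 99.5% — a fitted asymptote never literally reaches 100%; both
thresholds are configurable) interpolate linearly between grid points.

**Decline onset.** The decline is *detected* as the first grid day after
the peak at which the curve has dropped below `(1 − δ)·peak` (δ = 0.01
default) and stays below for ≥ 3 grid points. The detected crossing,
however, is a biased estimate of when the decline *starts*: it lags the
true kink by `δ·peak/rate` for slow declines, and for smoothed fits it can
lead it, because LOWESS rounds the plateau-decline corner over half a
window and the smoothed ripple inflates the peak used in the threshold.
The reported day is therefore the intersection of the post-corner decline
trend (a line fitted to the curve from one smoothing half-window past the
crossing to the end of the season) with the plateau level: for a curve
that is exactly flat until day *d* and linear afterwards this returns *d*
regardless of the decline rate, and in the Monte-Carlo study below it
removes a ~2–5 day early bias. If the tail segment is too short (< 3 days)
or not actually declining, the raw crossing day is returned.

Span for onset extraction: a span-0.5 window on a ~26-point seasonal
series is ≈ 35 days wide — wider than the whole post-onset segment when
senescence starts ~2 weeks before the last flight — so the onset study
uses span 0.3, whose window is shorter than the feature being located.
This is a resolution argument, not a tuning: peak-day and CC50 extraction,
which locate broad features, keep the 0.5 default.

## Canopy indices and digital biomass

ExG = `2G − (R + B)` on (H, W, 4) R,G,B,NIR images in [0, 1]; vegetation =
`ExG > t`. The default threshold is Otsu's criterion maximized exactly
over sorted-data splits (threshold at the midpoint of the optimal split)
rather than over histogram bins: for cleanly separable two-class images
the binned version resolves the flat inter-class tie to a bin edge and can
clip the lower class by a few pixels, which matters when coverage is
required to be exact on noise-free synthetic images. A fixed threshold
(`fixed:<t>`) is available; a constant index array falls back to 0 with a
warning. Coverage is the percent of vegetation pixels inside a half-open
rectangular plot boundary. NDVI = `(NIR − R)/(NIR + R)`, undefined pixels
masked; zonal statistic mean (default) or median.

Digital biomass divides the occupied-voxel volume by the plot ground area
(m³ m⁻²). The voxel grid is anchored at the cloud's minimum corner; a
voxel is occupied if ≥ 1 point falls in it; points on the far boundary are
assigned to the last voxel layer, so a box whose extent is an exact
multiple of the voxel size occupies exactly `extent/size` voxels per axis.
Discretization error is bounded by the one-voxel surface shell.

## FvCB fitting

`A = min(Wc, Wj) − Rd`, with Rubisco kinetics (Γ*, Kc, Ko at 25 °C and
their activation energies) and the Vcmax/J/Rd temperature responses
transcribed in `canopytrial/_bernacchi.py` (Arrhenius form,
`f(T) = f₂₅·exp(Ha/R·(1/298.15 − 1/T))`; O = 210 mmol mol⁻¹). Mesophyll
conductance is treated as infinite, so parameters are apparent, Ci-based
values. TPU limitation is not modelled; the measurement protocol tops out
at 1,800 ppm, and its three 400-ppm records are kept as independent
observations.

Estimation minimizes RSS — maximum likelihood under Gaussian error — with
Nelder-Mead from five starts (a coarse grid over Vcmax ∈ [20, 250],
J ∈ [40, 400], Rd ∈ [0.1, 5], plus seeded jitter for extra starts),
tolerances 1e-8. Parameters are estimated at the curve's mean leaf
temperature and divided by their Arrhenius factors to report 25 °C values.
Fits need ≥ 5 distinct Ci points; if no start converges the best-found
parameters are returned with `converged=False`.

## Yield–LAI optimum

Linear and quadratic OLS fits per stratum, compared by AIC, BIC, R² and
RMSE (same Gaussian-profile convention as above, `k = 3` and `4`); overall
pick by AIC with parsimony breaking exact ties. The optimum is the vertex
`−b₁/(2b₂)`, valid only for concave fits (`b₂ < 0`) and flagged
"extrapolated" outside the observed LAI range.

## Synthetic-trial generator

The generator emulates the structure the analysis assumes: MAD layouts
(default 5×5 blocks; strata of 5–10 blocks at two locations × two row
spacings); plot values as genotype effect + additive block-row/column
offsets + Gaussian noise (an optional smooth 2-D trend probes sub-block
structure); sigmoidal, concave and rise-plateau-decline time courses;
two-class vegetation/soil images whose ExG clusters are separable by
construction and whose vegetation-pixel count is exactly
`round(coverage·H·W)`; uniform box point clouds; FvCB-generated A-Ci
curves at the 14-setpoint protocol; and a two-component leaf-ratio mixture
(means 1.3 and 2.4 for broad and narrow leaves). Default trait scales
(peak LAI ≈ 9–10, yields ≈ 5,500–6,300 kg ha⁻¹, Vcmax25 80–160
µmol m⁻² s⁻¹, leaf temperature 28 °C) are realistic for Midwest soybean
trials.

What the generator does *not* emulate — and therefore what passing tests
do not demonstrate about real data: sub-plot geometry (each plot is one
grid cell; the real 4-row plots with alleys are not modelled),
non-additive or anisotropic spatial structure, measurement-day
irregularity, heteroscedastic or autocorrelated noise, mixed
vegetation/soil boundary pixels, LiDAR occlusion and leaf-angle effects
on point clouds, and stomatal patchiness in gas exchange.

## Validation studies (scripts/acceptance.py, tests/test_acceptance.py)

Problem sizes were chosen to give stable rates while keeping a full run
under a minute: 50 random trials for oracle equivalence (loop-based
recomputation, tolerance 1e-9 relative); 200 trials for the stochastic RE
study (block-gradient SD 3× the noise SD); 200 series per trait family
for temporal recovery (concave LAI: peak day 70, noise 0.15, 20 samples;
logistic CC: midpoint 38, noise 2 points; NDVI: plateau 0.9, decline
0.012 day⁻¹ from day 80, noise 0.01, 26 samples); 200 A-Ci curves at
noise SD 0.5 µmol m⁻² s⁻¹; 200 strata of n = 150 for vertex recovery
(true vertex 10.2, curvature 60 kg ha⁻¹ LAI⁻², yield noise 150 kg ha⁻¹).
All randomness flows from the `--seed` argument.

## Known limitations

* Method I cannot remove within-block spatial variation (block-grid
  resolution is a property of the design, not the implementation).
* The Method III intercept `α` shifts the adjusted scale by construction;
  comparisons across methods should use RE, not raw means.
* LOWESS information criteria rest on a linear-smoother edf approximation;
  with robustifying iterations the smoother is only approximately linear.
* The logistic model is a growth model; declining series are reported as
  non-converged rather than fitted with a negative rate.
* A-Ci fitting assumes homoscedastic Gaussian error and does not estimate
  TPU, stomatal or mesophyll conductance.
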