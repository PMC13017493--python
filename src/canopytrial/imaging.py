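"""Canopy coverage, NDVI and voxel-grid digital biomass.

Vegetation is separated from soil with the Excess Green index
``ExG = 2G - (R + B)`` followed by thresholding (Otsu by default); canopy
coverage is the percentage of vegetation pixels inside a plot boundary.
NDVI is ``(NIR - R) / (NIR + R)`` with mean (default) or median zonal
statistics.  Digital biomass is the plot's occupied voxel volume divided
by its ground area (m3 m-2), a voxel being occupied when at least one
point of the canopy point cloud falls inside it.

Images are (H, W, 4) arrays, channels R, G, B, NIR in [0, 1].  Plot
boundaries are half-open pixel rectangles ``(r0, r1, c0, c1)``.
"""

from __future__ import annotations

import warnings

import numpy as np

from canopytrial.synthetic import PointCloud

Boundary = tuple[int, int, int, int]  # (r0, r1, c0, c1), half-open


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 4:
        raise ValueError("expected an (H, W, 4) image with channels R, G, B, NIR")
    return image


def _check_boundary(shape: tuple[int, ...], boundary: Boundary | None) -> Boundary:
    h, w = shape[:2]
    if boundary is None:
        return (0, h, 0, w)
    r0, r1, c0, c1 = boundary
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"boundary {boundary} invalid or empty for image {h}x{w}")
    return boundary


def _otsu_exact(values: np.ndarray) -> float:
    """Otsu's threshold evaluated at data resolution.

    Maximizes the between-class variance over every split of the sorted
    values rather than over histogram bins, so well-separated classes are
    recovered exactly (the histogram version resolves the inter-class tie
    to a bin edge, which can clip the lower class at bin resolution).
    Agrees with :func:`skimage.filters.threshold_otsu` up to bin width.
    """
    v = np.sort(values)
    n = v.size
    k = np.arange(1, n)
    csum = np.cumsum(v)
    mu0 = csum[:-1] / k
    mu1 = (csum[-1] - csum[:-1]) / (n - k)
    w0 = k / n
    crit = w0 * (1.0 - w0) * (mu0 - mu1) ** 2
    best = int(np.argmax(crit))
    return 0.5 * (float(v[best]) + float(v[best + 1]))


def excess_green(image: np.ndarray) -> np.ndarray:
    """Per-pixel Excess Green index, 2G - (R + B)."""
    image = _check_image(image)
    return 2.0 * image[:, :, 1] - (image[:, :, 0] + image[:, :, 2])


def segment_vegetation(index: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Threshold an index array into a vegetation mask (``index > t``).

    ``method`` is ``"otsu"`` or ``"fixed:<t>"``.  A constant array has no
    Otsu threshold; the fall-back is a fixed threshold of 0 with a
    warning.
    """
    index = np.asarray(index, dtype=float)
    if not np.all(np.isfinite(index)):
        raise ValueError("index array must be finite")
    if method == "otsu":
        if np.ptp(index) == 0:
            warnings.warn("constant index array; falling back to fixed threshold 0")
            t = 0.0
        else:
            t = _otsu_exact(index.ravel())
    elif method.startswith("fixed:"):
        t = float(method.split(":", 1)[1])
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    return index > t


def canopy_coverage(mask: np.ndarray, boundary: Boundary | None = None) -> float:
    """Percent vegetation pixels inside the (half-open) plot boundary."""
    mask = np.asarray(mask, dtype=bool)
    r0, r1, c0, c1 = _check_boundary(mask.shape, boundary)
    zone = mask[r0:r1, c0:c1]
    return 100.0 * float(zone.sum()) / zone.size


def ndvi(image: np.ndarray) -> np.ndarray:
    """Per-pixel (NIR - R)/(NIR + R), NaN where NIR + R = 0."""
    image = _check_image(image)
    nir, red = image[:, :, 3], image[:, :, 0]
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), np.nan)
    return out


def zonal_ndvi(
    image: np.ndarray, boundary: Boundary | None = None, statistic: str = "mean"
) -> float:
    """Zonal NDVI statistic over a plot boundary (``mean`` default, or ``median``)."""
    arr = ndvi(image)
    r0, r1, c0, c1 = _check_boundary(arr.shape, boundary)
    zone = arr[r0:r1, c0:c1]
    zone = zone[np.isfinite(zone)]
    if zone.size == 0:
        raise ValueError("boundary contains no valid NDVI pixels")
    if statistic == "mean":
        return float(zone.mean())
    if statistic == "median":
        return float(np.median(zone))
    raise ValueError(f"unknown statistic {statistic!r}")


def voxel_count(points: np.ndarray, voxel_size_m: float) -> int:
    """Number of occupied voxels; grid anchored at the cloud's minimum corner.

    Points landing exactly on the far boundary of the last voxel layer are
    assigned to that layer (indices clipped), so a box whose extent is an
    exact multiple of the voxel size occupies exactly extent/size voxels
    per axis.
    """
    if voxel_size_m <= 0:
        raise ValueError("voxel size must be positive")
    if points.shape[0] == 0:
        return 0
    origin = points.min(axis=0)
    extent = points.max(axis=0) - origin
    n_vox = np.maximum(1, np.ceil(extent / voxel_size_m - 1e-12).astype(int))
    idx = np.floor((points - origin) / voxel_size_m).astype(int)
    idx = np.minimum(idx, n_vox - 1)
    return int(np.unique(idx, axis=0).shape[0])


def digital_biomass(cloud: PointCloud, voxel_size_m: float = 0.05) -> float:
    """Canopy volume per ground area (m3 m-2) from the occupied-voxel grid.

    ``volume = occupied voxels x voxel_size^3``; an empty cloud has zero
    biomass.
    """
    n = voxel_count(cloud.points, voxel_size_m)
    return n * voxel_size_m**3 / cloud.footprint_area


def plot_indices(
    image: np.ndarray,
    boundary: Boundary | None = None,
    segmentation: str = "otsu",
    ndvi_statistic: str = "mean",
) -> dict[str, float]:
    """Canopy coverage (%) and zonal NDVI of one plot image."""
    mask = segment_vegetation(excess_green(image), method=segmentation)
    return {
        "canopy_coverage": canopy_coverage(mask, boundary),
        "ndvi": zonal_ndvi(image, boundary, statistic=ndvi_statistic),
    }
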