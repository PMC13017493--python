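"""File I/O for plot tables, trait series, rasters and point clouds.

Tables are plain CSV (pandas).  Plot images travel as float32 4-band TIFF
(exact) or 16-bit RGBA PNG (quantized); point clouds as whitespace XYZ
text or PLY.  Ground-truth sidecars are YAML.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml


def write_plot_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_plot_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_image(image: np.ndarray, path) -> None:
    """Write an (H, W, 4) float image: .tif keeps float32, .png quantizes to 8 bit."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.astype(np.float32), photometric="rgb")
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, np.round(np.clip(image, 0, 1) * 255).astype(np.uint8))
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")


def read_image(path) -> np.ndarray:
    """Read a 4-band raster back to float in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path).astype(float)
    else:
        raw = iio.imread(path)
        arr = raw.astype(float)
        if arr.max() > 1.0:
            arr = arr / 65535.0 if raw.dtype.itemsize > 1 else arr / 255.0
    if arr.ndim != 3 or arr.shape[2] != 4:
        raise ValueError(f"{path} is not a 4-band raster")
    return arr


def write_cloud(points: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(points, dtype=float).reshape(-1, 3), fmt="%.6f")


def read_cloud(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        import trimesh

        return np.asarray(trimesh.load(str(path)).vertices, dtype=float)
    data = np.loadtxt(path, dtype=float)
    return data.reshape(-1, 3)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
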