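"""Spectral indices: NDVI, NDWI, and the pre/post-harvest NDVI difference.

NDVI = (NIR − Red)/(NIR + Red) and NDWI = (Green − NIR)/(Green + NIR) are the
same normalized-difference functional with different band roles; both live in
[−1, 1]. DiffNDVI = NDVI(pre-harvest) − NDVI(post-harvest) flags the abrupt
vegetation loss of harvested paddy rice and lives in [−2, 2].

Zero denominators (both bands zero) yield nodata (NaN), never 0: an index of
0 is a meaningful value and must not be aliased. Integer digital-number
rasters are rescaled to reflectance with ``scale`` (Sentinel-2 convention:
1/10000).
"""

from __future__ import annotations

import numpy as np

from .raster import Grid, require_aligned

S2_DN_SCALE = 1e-4


def _as_reflectance(grid: Grid, scale: float | None) -> np.ndarray:
    vals = grid.values
    valid = grid.valid_mask()
    if np.issubdtype(vals.dtype, np.integer):
        out = vals.astype(np.float64) * (S2_DN_SCALE if scale is None else scale)
    else:
        out = vals.astype(np.float64, copy=True)
        if scale is not None:
            out = out * scale
    out[~valid] = np.nan
    if np.nanmin(out, initial=0.0) < 0:
        raise ValueError("reflectance bands must be non-negative")
    return out


def normalized_difference(a: Grid, b: Grid, scale: float | None = None) -> Grid:
    """(a − b)/(a + b) per pixel, NaN where undefined or either input is nodata."""
    require_aligned(a, b)
    av = _as_reflectance(a, scale)
    bv = _as_reflectance(b, scale)
    denom = av + bv
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (av - bv) / denom, np.nan)
    return a.like(out, nodata=float("nan"))


def compute_ndvi(nir: Grid, red: Grid, scale: float | None = None) -> Grid:
    """Normalized difference vegetation index, (NIR − Red)/(NIR + Red)."""
    return normalized_difference(nir, red, scale=scale)


def compute_ndwi(green: Grid, nir: Grid, scale: float | None = None) -> Grid:
    """Normalized difference water index, (Green − NIR)/(Green + NIR)."""
    return normalized_difference(green, nir, scale=scale)


def compute_diff(ndvi_t1: Grid, ndvi_t2: Grid) -> Grid:
    """Pre-harvest minus post-harvest NDVI; NaN propagates from either date."""
    require_aligned(ndvi_t1, ndvi_t2)
    a = np.where(ndvi_t1.valid_mask(), ndvi_t1.values.astype(np.float64), np.nan)
    b = np.where(ndvi_t2.valid_mask(), ndvi_t2.values.astype(np.float64), np.nan)
    return ndvi_t1.like(a - b, nodata=float("nan"))
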