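"""Rice-mask extraction: threshold DiffNDVI, then remove water-edge pixels.

A pixel enters the initial mask when its DiffNDVI strictly exceeds the
calibrated threshold. Shorelines where the water boundary moved between the
two dates mimic that drop (vegetated shore at t1, water at t2); those pixels
are cleared wherever the pre-harvest NDWI falls inside the calibrated
water-edge interval (closed on both ends).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import WaterEdgeRange
from .raster import Grid, require_aligned

logger = logging.getLogger(__name__)


@dataclass
class RiceMask:
    """Binary rice raster with its extraction provenance."""

    mask: Grid  # uint8, 1 = rice, 0 = other
    threshold_used: float
    n_initial_pixels: int
    n_removed_edge_pixels: int = 0

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.mask.values == 1))

    @property
    def removed_fraction(self) -> float:
        if self.n_initial_pixels == 0:
            return 0.0
        return self.n_removed_edge_pixels / self.n_initial_pixels

    def area_km2(self) -> float:
        return self.n_pixels * self.mask.pixel_area / 1e6


@dataclass(frozen=True)
class AreaSummary:
    n_pixels: int
    pixel_area_m2: float
    area_km2: float
    fraction_of_study_area: float | None = None


def extract_initial(diff: Grid, threshold: float) -> RiceMask:
    """Initial mask: DiffNDVI strictly greater than the threshold.

    Nodata pixels are 0 in the mask; their count is logged. Ties at the
    threshold are excluded ("greater than", not "at least").
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    valid = diff.valid_mask()
    if not valid.any():
        raise ValueError("DiffNDVI grid contains no valid pixels")
    n_nodata = int(valid.size - valid.sum())
    if n_nodata:
        logger.info("extract_initial: %d nodata pixels set to 0 in the mask", n_nodata)
    vals = np.where(valid, diff.values, -np.inf)
    mask = (vals > threshold).astype(np.uint8)
    return RiceMask(
        mask=diff.like(mask, nodata=None),
        threshold_used=float(threshold),
        n_initial_pixels=int(mask.sum()),
    )


def remove_water_edge(rice: RiceMask, ndwi_preharvest: Grid,
                      edge_range: WaterEdgeRange) -> RiceMask:
    """Clear mask pixels whose NDWI lies in the water-edge interval.

    Returns a new mask (subset of the input); the removal count and fraction
    accumulate against the initial pixel count.
    """
    require_aligned(rice.mask, ndwi_preharvest)
    in_range = edge_range.contains(ndwi_preharvest.values) & ndwi_preharvest.valid_mask()
    to_remove = (rice.mask.values == 1) & in_range
    n_removed = int(to_remove.sum())
    new_mask = rice.mask.values.copy()
    new_mask[to_remove] = 0
    logger.info("remove_water_edge: removed %d of %d initial rice pixels (%.2f%%)",
                n_removed, rice.n_initial_pixels,
                100.0 * n_removed / max(rice.n_initial_pixels, 1))
    return RiceMask(
        mask=rice.mask.like(new_mask.astype(np.uint8), nodata=None),
        threshold_used=rice.threshold_used,
        n_initial_pixels=rice.n_initial_pixels,
        n_removed_edge_pixels=rice.n_removed_edge_pixels + n_removed,
    )


def area_stats(rice: RiceMask, study_area_km2: float | None = None) -> AreaSummary:
    """Mask area from the pixel count and the (square) pixel footprint."""
    pixel_area = rice.mask.pixel_size ** 2
    n = rice.n_pixels
    area = n * pixel_area / 1e6
    frac = None if study_area_km2 is None else area / study_area_km2
    return AreaSummary(n_pixels=n, pixel_area_m2=pixel_area, area_km2=area,
                       fraction_of_study_area=frac)
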