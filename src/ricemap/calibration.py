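"""Threshold calibration from sample polygons.

Two calibrations drive the extraction:

* the DiffNDVI rice threshold — each rice sample polygon is split into a
  10 m boundary ring (mixed pixels) and its interior (pure rice); pixels are
  pooled across all samples per zone and the threshold is mean − k·SD
  (k = 3). The boundary threshold is the operational one; the interior
  threshold is reported for audit but not applied.
* the NDWI water-edge interval — 2 m two-sided ribbons around water-edge
  sample lines select the land/water mixed pixels; the interval is the
  pooled mean ± k·SD. Pixels of the initial rice mask whose pre-harvest NDWI
  falls in this interval are shoreline artifacts, not rice.

Sample standard deviation (n − 1) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from shapely.geometry.base import BaseGeometry

from .raster import Grid, inward_buffer_split, pixels_in_edge_ribbon, pixels_in_zone

ZoneKind = Literal["boundary", "interior", "edge_ribbon"]


@dataclass(frozen=True)
class ZoneStats:
    """Pooled pixel statistics of one zone class."""

    mean: float
    sd: float
    n_pixels: int
    zone_kind: ZoneKind

    @classmethod
    def from_values(cls, values, zone_kind: ZoneKind) -> "ZoneStats":
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            raise ValueError(f"no valid pixels in the {zone_kind} zone")
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        return cls(mean=float(values.mean()), sd=sd, n_pixels=int(values.size),
                   zone_kind=zone_kind)

    def lower(self, k_sigma: float) -> float:
        return self.mean - k_sigma * self.sd

    def upper(self, k_sigma: float) -> float:
        return self.mean + k_sigma * self.sd


@dataclass(frozen=True)
class DiffThreshold:
    """mean − k·SD thresholds for the boundary ring and the interior."""

    boundary_threshold: float
    interior_threshold: float
    k_sigma: float
    boundary_stats: ZoneStats
    interior_stats: ZoneStats

    @property
    def operational(self) -> float:
        """The threshold actually applied: the boundary one."""
        return self.boundary_threshold

    def to_dict(self) -> dict:
        return {
            "boundary_threshold": self.boundary_threshold,
            "interior_threshold": self.interior_threshold,
            "k_sigma": self.k_sigma,
            "boundary": vars(self.boundary_stats).copy(),
            "interior": vars(self.interior_stats).copy(),
        }


@dataclass(frozen=True)
class WaterEdgeRange:
    """NDWI interval mean ± k·SD of pooled water-edge ribbon pixels."""

    low: float
    high: float
    k_sigma: float
    stats: ZoneStats

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("interval low must not exceed high")

    def contains(self, values) -> np.ndarray:
        """Closed-interval membership, elementwise."""
        v = np.asarray(values, dtype=float)
        return (v >= self.low) & (v <= self.high)

    def to_dict(self) -> dict:
        return {"low": self.low, "high": self.high, "k_sigma": self.k_sigma,
                "stats": vars(self.stats).copy()}

    @classmethod
    def from_stats(cls, stats: ZoneStats, k_sigma: float = 3.0) -> "WaterEdgeRange":
        return cls(low=stats.lower(k_sigma), high=stats.upper(k_sigma),
                   k_sigma=k_sigma, stats=stats)


def threshold_from_stats(stats: ZoneStats, k_sigma: float = 3.0) -> float:
    """The mean − k·SD rule on one zone's statistics."""
    return stats.lower(k_sigma)


def calibrate_diff_threshold(
    diff: Grid,
    rice_polygons: Iterable[BaseGeometry],
    buffer_depth: float = 10.0,
    k_sigma: float = 3.0,
    pooled: bool = True,
) -> DiffThreshold:
    """Derive the DiffNDVI threshold from rice-field sample polygons.

    ``pooled=True`` (default) computes one mean/SD over all pixels of all
    samples per zone class; ``pooled=False`` averages per-sample means and
    SDs instead (each sample weighted equally).
    """
    polygons = list(rice_polygons)
    if not polygons:
        raise ValueError("need at least one rice sample polygon")
    per_zone: dict[ZoneKind, list[np.ndarray]] = {"boundary": [], "interior": []}
    for poly in polygons:
        split = inward_buffer_split(poly, buffer_depth)
        per_zone["boundary"].append(pixels_in_zone(diff, split.boundary_zone))
        if not split.interior_zone.is_empty:
            per_zone["interior"].append(pixels_in_zone(diff, split.interior_zone))

    def zone_stats(kind: ZoneKind) -> ZoneStats:
        chunks = [c for c in per_zone[kind] if c.size > 0]
        if not chunks:
            raise ValueError(f"no pixels found in any {kind} zone of the rice samples")
        if pooled:
            return ZoneStats.from_values(np.concatenate(chunks), kind)
        per = [ZoneStats.from_values(c, kind) for c in chunks]
        return ZoneStats(
            mean=float(np.mean([s.mean for s in per])),
            sd=float(np.mean([s.sd for s in per])),
            n_pixels=int(sum(s.n_pixels for s in per)),
            zone_kind=kind,
        )

    b, i = zone_stats("boundary"), zone_stats("interior")
    return DiffThreshold(
        boundary_threshold=b.lower(k_sigma),
        interior_threshold=i.lower(k_sigma),
        k_sigma=k_sigma, boundary_stats=b, interior_stats=i,
    )


def calibrate_water_edge_range(
    ndwi: Grid,
    edge_samples: Iterable[BaseGeometry],
    buffer_width: float = 2.0,
    k_sigma: float = 3.0,
) -> WaterEdgeRange:
    """Derive the NDWI water-edge interval from shoreline sample lines.

    ``ndwi`` should be computed from the pre-harvest image — the mixed
    pixels are shore-like on that date.
    """
    samples: Sequence[BaseGeometry] = list(edge_samples)
    if not samples:
        raise ValueError("need at least one water-edge sample")
    chunks = [pixels_in_edge_ribbon(ndwi, geom, buffer_width) for geom in samples]
    pooled = np.concatenate([c for c in chunks if c.size > 0] or [np.empty(0)])
    stats = ZoneStats.from_values(pooled, "edge_ribbon")  # raises if empty
    return WaterEdgeRange.from_stats(stats, k_sigma)
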