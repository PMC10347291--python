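"""Synthetic Sentinel-2-like scenes with known ground truth.

The generator emulates everything the extraction pipeline consumes:

* a pre/post-harvest pair of 3-band (green, red, NIR) 10 m reflectance
  rasters covering five land-cover classes — rice fields, dry land, water,
  construction land, forest/grassland — whose per-class NDVI drops between
  the two dates default to the observed values 0.33 / 0.09 / 0.04 / 0.03 /
  0.08;
* a water body whose shoreline advances landward between the dates, so a
  ribbon of pixels is vegetated-shore-mixed at t1 and open water at t2 —
  the "water edge effect" false-positive mechanism (mixed pixels are a
  50/50 linear reflectance blend);
* rice sample polygons (33) and water-edge sample lines (20) for threshold
  calibration, drawn inside the truth regions;
* harvest-period survey samples generated from the published plane
  y = 8.077·lat + 0.056·alt − 245.040 plus Gaussian noise (SD 2.749 days).

Reflectances per class are derived by inverting the NDVI/NDWI definitions at
a chosen red-band base value; noise is added to reflectance (not to the
indices), which induces realistic heteroscedastic index noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, box

from .raster import Grid, GridTransform

CLASS_CODES = {"rice": 1, "dry": 2, "water": 3, "construction": 4, "forest": 5}


@dataclass(frozen=True)
class ClassSpec:
    """Spectral targets of one land-cover class.

    ``pre_ndvi`` and ``ndwi`` are the noise-free index targets on the
    pre-harvest date; ``drop`` is the NDVI decrease to the post-harvest date
    (NDWI target is held constant across dates). ``red_base`` anchors the
    red-band reflectance from which the other bands are derived.
    """

    name: str
    pre_ndvi: float
    drop: float
    ndwi: float
    red_base: float

    @property
    def code(self) -> int:
        return CLASS_CODES[self.name]

    @property
    def post_ndvi(self) -> float:
        return self.pre_ndvi - self.drop


DEFAULT_CLASSES = {
    "rice": ClassSpec("rice", pre_ndvi=0.80, drop=0.33, ndwi=-0.60, red_base=0.10),
    "dry": ClassSpec("dry", pre_ndvi=0.78, drop=0.09, ndwi=-0.40, red_base=0.10),
    "water": ClassSpec("water", pre_ndvi=-0.30, drop=0.04, ndwi=0.55, red_base=0.20),
    "construction": ClassSpec("construction", pre_ndvi=0.25, drop=0.03, ndwi=-0.15, red_base=0.18),
    "forest": ClassSpec("forest", pre_ndvi=0.85, drop=0.08, ndwi=-0.55, red_base=0.05),
}


def reflectance_for_targets(ndvi_target: float, ndwi_target: float,
                            red_base: float) -> tuple[float, float, float]:
    """Invert the index definitions: (green, red, nir) hitting both targets.

    nir = red·(1+NDVI)/(1−NDVI) and green = nir·(1+NDWI)/(1−NDWI). Values
    are clipped into (0, 1]; if clipping would shift either recomputed index
    by more than 1e-6 the target pair is infeasible and an error is raised.
    """
    if not (abs(ndvi_target) < 1 and abs(ndwi_target) < 1):
        raise ValueError("index targets must lie strictly inside (-1, 1)")
    if not 0 < red_base < 1:
        raise ValueError("red_base must lie in (0, 1)")
    red = red_base
    nir = red * (1 + ndvi_target) / (1 - ndvi_target)
    green = nir * (1 + ndwi_target) / (1 - ndwi_target)
    eps = 1e-12
    g, n = float(np.clip(green, eps, 1.0)), float(np.clip(nir, eps, 1.0))
    ndvi_back = (n - red) / (n + red)
    ndwi_back = (g - n) / (g + n)
    if abs(ndvi_back - ndvi_target) > 1e-6 or abs(ndwi_back - ndwi_target) > 1e-6:
        raise ValueError(
            f"infeasible target pair (ndvi={ndvi_target}, ndwi={ndwi_target}, "
            f"red_base={red_base}): bands leave (0, 1]"
        )
    return g, red, n


@dataclass
class SceneConfig:
    """Layout and spectral parameters of a synthetic scene.

    The default 240x240 10 m scene is banded north to south: construction,
    dry land, rice, forest/grassland, then water with a sinusoidal t1
    shoreline that advances landward by ``water_shift_px`` pixels at t2.
    """

    width: int = 240
    height: int = 240
    pixel_size: float = 10.0
    classes: dict[str, ClassSpec] = field(default_factory=lambda: dict(DEFAULT_CLASSES))
    noise_sd: float = 0.01
    water_shift_px: int = 1
    scatter_fraction: float = 0.01  # isolated rice pixels sprinkled in dry land
    n_rice_samples: int = 33
    n_edge_samples: int = 20
    rice_sample_px: int = 5  # side of each square rice sample, in pixels
    shore_amplitude_px: int = 3
    shore_period_px: int = 48
    origin: tuple[float, float] = (500000.0, 3300000.0)
    crs: str = "EPSG:32648"
    seed: int = 0

    def transform(self) -> GridTransform:
        return GridTransform.from_origin(self.origin[0], self.origin[1], self.pixel_size)


@dataclass
class SyntheticScene:
    """A generated scene: bands, truth, samples, and the edge-pixel flags."""

    pre: dict[str, Grid]   # keys: green, red, nir
    post: dict[str, Grid]
    truth: Grid            # class codes 1-5 (t1 classes; mixed shore keeps its land code)
    edge_truth: Grid       # 1 where a pixel is land-mixed at t1 and water at t2
    rice_sample_polygons: list[Polygon]
    water_edge_sample_lines: list[LineString]
    config: SceneConfig

    @property
    def truth_rice(self) -> Grid:
        """Binary truth: 1 = rice."""
        return self.truth.like((self.truth.values == CLASS_CODES["rice"]).astype(np.uint8))


def _band_layout(cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class-code rasters at t1 and t2, plus the mixed-shore flag."""
    h, w = cfg.height, cfg.width
    if h < 60 or w < 60:
        raise ValueError(f"scene {w}x{h} too small for the five-class layout")
    codes1 = np.zeros((h, w), dtype=np.uint8)
    r1 = round(h * 1 / 6)   # construction
    r2 = round(h * 2 / 6)   # dry land
    r3 = round(h * 4 / 6)   # rice
    water_top = h - round(h / 6)  # nominal top of the water band
    codes1[:r1] = CLASS_CODES["construction"]
    codes1[r1:r2] = CLASS_CODES["dry"]
    codes1[r2:r3] = CLASS_CODES["rice"]
    codes1[r3:] = CLASS_CODES["forest"]
    cols = np.arange(w)
    shore = water_top + np.round(
        cfg.shore_amplitude_px * np.sin(2 * np.pi * cols / cfg.shore_period_px)
    ).astype(int)
    shore = np.clip(shore, r3 + cfg.water_shift_px + 1, h - 2)
    rows = np.arange(h)[:, None]
    codes1[rows >= shore[None, :]] = CLASS_CODES["water"]
    # t2: shoreline advances landward (up) by the shift
    codes2 = codes1.copy()
    mixed = (rows >= (shore - cfg.water_shift_px)[None, :]) & (rows < shore[None, :])
    codes2[mixed] = CLASS_CODES["water"]
    return codes1, codes2, mixed.astype(np.uint8)


def _class_reflectances(cfg: SceneConfig, date: str) -> dict[int, tuple[float, float, float]]:
    out = {}
    for spec in cfg.classes.values():
        ndvi = spec.pre_ndvi if date == "pre" else spec.post_ndvi
        out[spec.code] = reflectance_for_targets(ndvi, spec.ndwi, spec.red_base)
    return out


def _rice_sample_polygons(cfg: SceneConfig, codes1: np.ndarray,
                          t: GridTransform) -> list[Polygon]:
    rice_rows = np.nonzero((codes1 == CLASS_CODES["rice"]).any(axis=1))[0]
    r_lo, r_hi = int(rice_rows.min()), int(rice_rows.max())
    side = cfg.rice_sample_px
    n = cfg.n_rice_samples
    ncols = math.ceil(math.sqrt(n * cfg.width / max(r_hi - r_lo + 1, 1)))
    ncols = max(1, min(ncols, (cfg.width - 2) // (side + 2)))
    nrows = math.ceil(n / ncols)
    if (r_hi - r_lo + 1) < nrows * (side + 2):
        raise ValueError("rice band too small for the requested sample polygons")
    polys = []
    for j in range(nrows):
        for i in range(ncols):
            if len(polys) >= n:
                break
            row0 = r_lo + 2 + j * ((r_hi - r_lo - side - 2) // max(nrows, 2) if nrows > 1 else 0)
            col0 = 2 + i * ((cfg.width - side - 4) // max(ncols - 1, 1) if ncols > 1 else 0)
            row0 = min(row0, r_hi - side + 1)
            x0, y0 = t.xy(row0, col0, offset="corner")
            x1, y1 = t.xy(row0 + side, col0 + side, offset="corner")
            polys.append(box(min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1)))
    return polys


def _edge_sample_lines(cfg: SceneConfig, mixed: np.ndarray,
                       t: GridTransform) -> list[LineString]:
    """Polylines through the centers of mixed-shore pixel runs.

    For each maximal run of columns whose mixed ribbon sits on the same row,
    a horizontal segment through those pixel centers is emitted; the sub-
    pixel 2 m calibration ribbon around these lines then contains exactly
    the mixed-pixel centers.
    """
    h, w = mixed.shape
    # representative (middle) mixed row per column
    rows = np.full(w, -1)
    for c in range(w):
        rr = np.nonzero(mixed[:, c])[0]
        if rr.size:
            rows[c] = rr[rr.size // 2]
    lines: list[LineString] = []
    c = 0
    while c < w:
        if rows[c] < 0:
            c += 1
            continue
        c0 = c
        while c + 1 < w and rows[c + 1] == rows[c0]:
            c += 1
        x0, y0 = t.xy(rows[c0], c0)
        x1, _ = t.xy(rows[c0], c)
        # extend past the end centers so flat caps keep them strictly inside
        ext = t.pixel_size * 0.3
        lines.append(LineString([(x0 - ext, y0), (x1 + ext, y0)]))
        c += 1
    if len(lines) < cfg.n_edge_samples:
        raise ValueError(
            f"shoreline produced only {len(lines)} edge runs, "
            f"{cfg.n_edge_samples} samples requested"
        )
    pick = np.linspace(0, len(lines) - 1, cfg.n_edge_samples).round().astype(int)
    return [lines[i] for i in np.unique(pick)]


def generate_scene(config: SceneConfig | None = None, seed: int | None = None) -> SyntheticScene:
    """Generate a seeded scene pair with truth and calibration samples."""
    cfg = config or SceneConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if cfg.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    t = cfg.transform()
    codes1, codes2, mixed = _band_layout(cfg)
    # sample polygons come from the contiguous rice band, before scatter
    rice_polys = _rice_sample_polygons(cfg, codes1, t)

    # scattered single-pixel rice patches in the dry-land band
    dry = codes1 == CLASS_CODES["dry"]
    n_scatter = int(round(cfg.scatter_fraction * dry.sum()))
    if n_scatter:
        rr, cc = np.nonzero(dry)
        pick = rng.choice(rr.size, size=n_scatter, replace=False)
        codes1[rr[pick], cc[pick]] = CLASS_CODES["rice"]
        codes2[rr[pick], cc[pick]] = CLASS_CODES["rice"]

    bands = {"pre": {}, "post": {}}
    for date, codes in (("pre", codes1), ("post", codes2)):
        refl = _class_reflectances(cfg, date)
        green = np.empty(codes.shape)
        red = np.empty(codes.shape)
        nir = np.empty(codes.shape)
        for code, (g, r, n) in refl.items():
            sel = codes == code
            green[sel], red[sel], nir[sel] = g, r, n
        if date == "pre":
            # mixed shoreline pixels: 50/50 blend of their land class and water
            land_refl_g, land_refl_r, land_refl_n = green.copy(), red.copy(), nir.copy()
            wg, wr, wn = refl[CLASS_CODES["water"]]
            sel = mixed.astype(bool)
            green[sel] = 0.5 * (land_refl_g[sel] + wg)
            red[sel] = 0.5 * (land_refl_r[sel] + wr)
            nir[sel] = 0.5 * (land_refl_n[sel] + wn)
        for name, arr in (("green", green), ("red", red), ("nir", nir)):
            if cfg.noise_sd > 0:
                arr = arr + rng.normal(0.0, cfg.noise_sd, arr.shape)
            arr = np.clip(arr, 1e-6, 1.0)
            bands[date][name] = Grid(arr, t, cfg.crs, nodata=None)

    truth = Grid(codes1, t, cfg.crs, nodata=None)
    edge_truth = Grid(mixed, t, cfg.crs, nodata=None)
    return SyntheticScene(
        pre=bands["pre"], post=bands["post"],
        truth=truth, edge_truth=edge_truth,
        rice_sample_polygons=rice_polys,
        water_edge_sample_lines=_edge_sample_lines(cfg, mixed, t),
        config=cfg,
    )


def generate_harvest_samples(
    n: int = 32,
    coef_lat: float = 8.077,
    coef_alt: float = 0.056,
    intercept: float = -245.040,
    noise_sd: float = 2.749,
    lat_range: tuple[float, float] = (28.5, 31.5),
    alt_range: tuple[float, float] = (150.0, 1200.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Survey samples from the harvest-day plane plus Gaussian noise.

    Latitude/altitude are uniform over ranges spanning a hilly subtropical
    rice region; the defaults replicate the published plane and its residual
    scale (SEE 2.749 days).
    """
    if n < 4:
        raise ValueError("need at least 4 samples")
    if lat_range[0] >= lat_range[1] or alt_range[0] >= alt_range[1]:
        raise ValueError("degenerate latitude or altitude range")
    rng = np.random.default_rng(seed)
    lat = rng.uniform(*lat_range, size=n)
    alt = rng.uniform(*alt_range, size=n)
    y = coef_lat * lat + coef_alt * alt + intercept
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"latitude": lat, "altitude": alt, "harvest_day": y})
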