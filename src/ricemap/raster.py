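"""Georeferenced raster and vector primitives.

A :class:`Grid` is a single 2-D band (reflectance, spectral index, or mask)
with a north-up affine transform and an EPSG coordinate system. GeoTIFF
serialisation is handled through :mod:`tifffile` using the standard GeoTIFF
tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the GDAL nodata
convention, so outputs open in QGIS/GDAL. Vector samples travel as GeoJSON
through :mod:`shapely`.

All geometric operations assume projected, metric coordinates; buffering in
geographic degrees is refused because buffer depths are given in meters.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

# GeoTIFF tag codes
_TAG_PIXELSCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODELTYPE = 1024
_KEY_RASTERTYPE = 1025
_KEY_GEOGRAPHIC_CS = 2048
_KEY_PROJECTED_CS = 3072

#: EPSG codes treated as geographic (degree) systems.
GEOGRAPHIC_EPSG = frozenset({4326, 4269, 4267, 4258, 4490})


def _epsg_code(crs: str) -> int:
    try:
        auth, code = str(crs).split(":")
        if auth.upper() != "EPSG":
            raise ValueError
        return int(code)
    except ValueError:
        raise ValueError(f"CRS must be an 'EPSG:nnnn' string, got {crs!r}") from None


def crs_is_geographic(crs: str) -> bool:
    return _epsg_code(crs) in GEOGRAPHIC_EPSG


@dataclass(frozen=True)
class GridTransform:
    """North-up affine map from (row, col) to projected (x, y).

    ``x = c + a * col`` and ``y = f + e * row`` with ``a > 0`` and ``e < 0``
    (row 0 is the north edge). Shear terms are not supported.
    """

    a: float  # pixel width (x units)
    c: float  # x of the outer corner of pixel (0, 0)
    e: float  # pixel height, negative for north-up
    f: float  # y of the outer corner of pixel (0, 0)

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.e < 0):
            raise ValueError("transform must be north-up with positive pixel width")

    @classmethod
    def from_origin(cls, west: float, north: float, pixel_size: float) -> "GridTransform":
        return cls(a=float(pixel_size), c=float(west), e=-float(pixel_size), f=float(north))

    @property
    def pixel_width(self) -> float:
        return self.a

    @property
    def pixel_height(self) -> float:
        return -self.e

    @property
    def pixel_size(self) -> float:
        if not math.isclose(self.a, -self.e, rel_tol=1e-9):
            raise ValueError("pixel size is not square")
        return self.a

    def xy(self, row, col, offset: str = "center"):
        """Projected coordinates of a pixel ('center' or 'corner')."""
        shift = 0.5 if offset == "center" else 0.0
        col = np.asarray(col, dtype=float) + shift
        row = np.asarray(row, dtype=float) + shift
        return self.c + self.a * col, self.f + self.e * row

    def rowcol(self, x, y):
        """Fractional (row, col) of projected coordinates."""
        col = (np.asarray(x, dtype=float) - self.c) / self.a
        row = (np.asarray(y, dtype=float) - self.f) / self.e
        return row, col


@dataclass
class Grid:
    """One georeferenced band: values + transform + CRS + nodata sentinel."""

    values: np.ndarray
    transform: GridTransform
    crs: str
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"Grid values must be 2-D, got shape {self.values.shape}")
        _epsg_code(self.crs)

    # -- basic geometry ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_size(self) -> float:
        return self.transform.pixel_size

    @property
    def pixel_area(self) -> float:
        return self.transform.pixel_width * self.transform.pixel_height

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        nrow, ncol = self.shape
        x0, y0 = self.transform.xy(0, 0, offset="corner")
        x1, y1 = self.transform.xy(nrow, ncol, offset="corner")
        return (min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1))

    def valid_mask(self) -> np.ndarray:
        """Boolean array: True where the pixel carries data."""
        v = self.values
        ok = np.ones(v.shape, dtype=bool)
        if np.issubdtype(v.dtype, np.floating):
            ok &= np.isfinite(v)
        if self.nodata is not None and not (
            isinstance(self.nodata, float) and math.isnan(self.nodata)
        ):
            ok &= v != self.nodata
        return ok

    def is_aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and math.isclose(self.transform.a, other.transform.a, rel_tol=1e-12)
            and math.isclose(self.transform.c, other.transform.c, rel_tol=1e-12, abs_tol=1e-6)
            and math.isclose(self.transform.e, other.transform.e, rel_tol=1e-12)
            and math.isclose(self.transform.f, other.transform.f, rel_tol=1e-12, abs_tol=1e-6)
        )

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """A new grid sharing this grid's georeferencing."""
        return Grid(values=values, transform=self.transform, crs=self.crs, nodata=nodata)


def require_aligned(*grids: Grid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.is_aligned_with(g):
            raise ValueError(
                "grids are not co-registered: "
                f"shape {first.shape} vs {g.shape}, crs {first.crs} vs {g.crs}"
            )


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _geotags(transform: GridTransform, crs: str, nodata) -> list:
    epsg = _epsg_code(crs)
    if epsg in GEOGRAPHIC_EPSG:
        model_type, cs_key = 2, _KEY_GEOGRAPHIC_CS
    else:
        model_type, cs_key = 1, _KEY_PROJECTED_CS
    keys = [
        (_KEY_MODELTYPE, 0, 1, model_type),
        (_KEY_RASTERTYPE, 0, 1, 1),  # PixelIsArea
        (cs_key, 0, 1, epsg),
    ]
    directory = [1, 1, 0, len(keys)]
    for k in keys:
        directory.extend(k)
    tags = [
        (_TAG_PIXELSCALE, 12, 3, (transform.pixel_width, transform.pixel_height, 0.0)),
        (_TAG_TIEPOINT, 12, 6, (0.0, 0.0, 0.0, transform.c, transform.f, 0.0)),
        (_TAG_GEOKEYS, 3, len(directory), tuple(directory)),
    ]
    if nodata is not None:
        txt = "nan" if (isinstance(nodata, float) and math.isnan(nodata)) else repr(nodata)
        tags.append((_TAG_GDAL_NODATA, 2, len(txt) + 1, txt))
    return tags


def write_raster(grid: Grid, path, bands: Sequence[Grid] | None = None) -> Path:
    """Write one grid (or several co-registered grids as bands) to GeoTIFF."""
    path = Path(path)
    all_bands = [grid] + list(bands or [])
    if len(all_bands) > 1:
        require_aligned(*all_bands)
        for b in all_bands[1:]:
            if (b.nodata is None) != (grid.nodata is None):
                raise ValueError("all bands must share the nodata convention")
        data = np.stack([b.values for b in all_bands], axis=-1)
    else:
        data = grid.values
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig="contig" if data.ndim == 3 else None,
        extratags=_geotags(grid.transform, grid.crs, grid.nodata),
    )
    return path


def _parse_geotags(page, path) -> tuple[GridTransform, str, float | None]:
    tags = page.tags
    scale = tags.get(_TAG_PIXELSCALE)
    tie = tags.get(_TAG_TIEPOINT)
    keys = tags.get(_TAG_GEOKEYS)
    if scale is None or tie is None or keys is None:
        raise ValueError(f"{path}: missing georeferencing (GeoTIFF tags not found)")
    sx, sy = float(scale.value[0]), float(scale.value[1])
    i, j, _, x, y, _ = (float(v) for v in tie.value[:6])
    # shift the tiepoint to pixel (0, 0) outer corner
    transform = GridTransform(a=sx, c=x - i * sx, e=-sy, f=y + j * sy)
    kv = list(keys.value)
    epsg = None
    n = kv[3]
    for k in range(n):
        key_id, _, _, val = kv[4 + 4 * k : 8 + 4 * k]
        if key_id in (_KEY_PROJECTED_CS, _KEY_GEOGRAPHIC_CS):
            epsg = int(val)
    if epsg is None:
        raise ValueError(f"{path}: no EPSG code in GeoKeyDirectory")
    nd_tag = tags.get(_TAG_GDAL_NODATA)
    nodata = None
    if nd_tag is not None:
        txt = str(nd_tag.value).strip().strip("\x00")
        nodata = float(txt)
    return transform, f"EPSG:{epsg}", nodata


def read_raster(path, band: int = 1) -> Grid:
    """Read one band (1-based index) of a GeoTIFF as a :class:`Grid`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        transform, crs, nodata = _parse_geotags(page, path)
    if data.ndim == 2:
        nbands = 1
        if band != 1:
            raise IndexError(f"{path}: band {band} out of range (1 band)")
        values = data
    else:
        # contig layout (rows, cols, bands)
        nbands = data.shape[-1]
        if not 1 <= band <= nbands:
            raise IndexError(f"{path}: band {band} out of range ({nbands} bands)")
        values = data[..., band - 1]
    return Grid(values=np.ascontiguousarray(values), transform=transform, crs=crs, nodata=nodata)


def read_bands(path) -> list[Grid]:
    """All bands of a GeoTIFF, in order."""
    first = read_raster(path, band=1)
    with tifffile.TiffFile(path) as tf:
        data = tf.pages[0].asarray()
    nbands = 1 if data.ndim == 2 else data.shape[-1]
    return [read_raster(path, band=i + 1) for i in range(nbands)]


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Geometries + per-feature properties + CRS, as read from GeoJSON."""

    geometries: list[BaseGeometry]
    properties: list[dict] = field(default_factory=list)
    crs: str | None = None

    def __post_init__(self) -> None:
        if not self.properties:
            self.properties = [{} for _ in self.geometries]

    def __len__(self) -> int:
        return len(self.geometries)

    def __iter__(self):
        return iter(self.geometries)


def read_vector(path) -> FeatureSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"vector file not found: {path}")
    if path.suffix.lower() in {".shp", ".shx", ".dbf"}:
        raise ValueError(
            f"{path}: ESRI Shapefile is not supported by this build; convert to GeoJSON"
        )
    with open(path) as fh:
        doc = json.load(fh)
    crs = None
    crs_member = doc.get("crs")
    if crs_member:
        name = crs_member.get("properties", {}).get("name", "")
        if "EPSG" in name.upper():
            crs = "EPSG:" + name.rsplit(":", 1)[-1].rsplit("::", 1)[-1]
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    geoms, props = [], []
    for f in feats:
        geoms.append(shape(f["geometry"]))
        props.append(f.get("properties") or {})
    return FeatureSet(geometries=geoms, properties=props, crs=crs)


def write_vector(path, geometries: Iterable[BaseGeometry],
                 properties: Sequence[dict] | None = None, crs: str | None = None) -> Path:
    path = Path(path)
    geometries = list(geometries)
    properties = list(properties) if properties is not None else [{} for _ in geometries]
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": p}
            for g, p in zip(geometries, properties, strict=True)
        ],
    }
    if crs:
        doc["crs"] = {"type": "name", "properties": {"name": f"urn:ogc:def:crs:EPSG::{_epsg_code(crs)}"}}
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path


# ---------------------------------------------------------------------------
# Geometry-to-pixel machinery
# ---------------------------------------------------------------------------

def _check_metric(grid_or_crs) -> None:
    crs = grid_or_crs.crs if isinstance(grid_or_crs, Grid) else grid_or_crs
    if crs is not None and crs_is_geographic(crs):
        raise ValueError(
            f"{crs} is a geographic (degree) system; reproject to projected meters "
            "before metric buffering/zonal operations"
        )


def pixels_in_zone(grid: Grid, zone: BaseGeometry, zone_crs: str | None = None) -> np.ndarray:
    """Values of all valid pixels whose *centers* fall inside ``zone``.

    Pixel membership is by center-in-polygon, matching the convention that a
    10 m buffer selects exactly one ring of 10 m pixels. An empty selection
    returns an empty array; severity is the caller's call.
    """
    if zone_crs is not None and zone_crs != grid.crs:
        raise ValueError(f"CRS mismatch: zone {zone_crs} vs grid {grid.crs}")
    if zone.is_empty:
        return np.empty(0, dtype=grid.values.dtype)
    nrow, ncol = grid.shape
    minx, miny, maxx, maxy = zone.bounds
    t = grid.transform
    # candidate window from the zone bounding box (centers only)
    c0 = max(0, int(math.floor((minx - t.c) / t.a - 0.5)))
    c1 = min(ncol - 1, int(math.ceil((maxx - t.c) / t.a - 0.5)))
    r0 = max(0, int(math.floor((maxy - t.f) / t.e - 0.5)))
    r1 = min(nrow - 1, int(math.ceil((miny - t.f) / t.e - 0.5)))
    if c1 < c0 or r1 < r0:
        return np.empty(0, dtype=grid.values.dtype)
    rows, cols = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    xs, ys = t.xy(rows.ravel(), cols.ravel())
    inside = shapely.contains_xy(zone, xs, ys).reshape(rows.shape)
    window = grid.values[r0 : r1 + 1, c0 : c1 + 1]
    valid = grid.valid_mask()[r0 : r1 + 1, c0 : c1 + 1]
    return window[inside & valid]


@dataclass(frozen=True)
class ZoneSplit:
    """A polygon split into its edge ring and inward-offset interior."""

    boundary_zone: BaseGeometry
    interior_zone: BaseGeometry


def _require_valid(geom: BaseGeometry) -> None:
    if geom is None or geom.is_empty or not geom.is_valid:
        raise ValueError("invalid or empty geometry")


def inward_buffer_split(polygon: BaseGeometry, depth: float) -> ZoneSplit:
    """Split a polygon into a boundary ring of width ``depth`` and its interior.

    The interior is the polygon eroded inward by ``depth`` meters; the
    boundary ring is the set difference. If the erosion empties the polygon
    the whole polygon is boundary.
    """
    _require_valid(polygon)
    if not depth > 0:
        raise ValueError(f"buffer depth must be > 0, got {depth}")
    interior = polygon.buffer(-depth)
    if interior.is_empty:
        return ZoneSplit(boundary_zone=polygon, interior_zone=interior)
    return ZoneSplit(boundary_zone=polygon.difference(interior), interior_zone=interior)


def two_sided_buffer(boundary: BaseGeometry, width: float) -> BaseGeometry:
    """Ribbon of all points within ``width`` meters of a line (both sides).

    Polygon input is taken to mean its boundary ring. Flat caps: the ribbon
    does not extend beyond the line ends.
    """
    _require_valid(boundary)
    if not width > 0:
        raise ValueError(f"buffer width must be > 0, got {width}")
    geom = boundary.boundary if boundary.geom_type in ("Polygon", "MultiPolygon") else boundary
    return geom.buffer(width, cap_style="flat")


def pixels_in_edge_ribbon(grid: Grid, boundary: BaseGeometry, width: float) -> np.ndarray:
    """Pixel values in the two-sided ribbon around a water-edge line.

    A sub-pixel ribbon (e.g. 2 m on 10 m pixels) can miss every pixel
    center; in that case the selection is retried with the ribbon dilated to
    one pixel diagonal so the pixels straddling the line are captured. The
    fallback is logged.
    """
    _check_metric(grid)
    ribbon = two_sided_buffer(boundary, width)
    values = pixels_in_zone(grid, ribbon)
    if values.size == 0:
        diag = grid.pixel_size * math.sqrt(2.0)
        if width < diag:
            logger.warning(
                "edge ribbon of width %.3g m selected no pixel centers; "
                "dilating to one pixel diagonal (%.3g m)", width, diag
            )
            values = pixels_in_zone(grid, two_sided_buffer(boundary, diag))
    return values
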