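"""End-to-end orchestration: scene → indices → calibrate → extract → validate.

One :func:`run_pipeline` call executes the full method in order, persisting
every intermediate raster and a machine-readable JSON report of all derived
numbers (thresholds, water-edge interval, areas, removal statistics,
accuracy metrics). Runs are deterministic under a fixed seed and config, and
individually resumable: an intermediate already present in the output
directory is reloaded instead of recomputed when ``resume=True``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
from shapely.geometry import Point

from . import __version__
from .calibration import calibrate_diff_threshold, calibrate_water_edge_range
from .extraction import area_stats, extract_initial, remove_water_edge
from .harvest import HarvestFit, fit_harvest_model
from .indices import compute_diff, compute_ndvi, compute_ndwi
from .raster import read_raster, read_vector, write_raster, write_vector
from .synthetic import SceneConfig, generate_harvest_samples, generate_scene
from .validation import (ConfusionMatrix, accuracy_metrics, assign_truth,
                         stratified_sample)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: either a simulation config (``scene``) or paths
    to real pre/post 3-band rasters plus sample/truth vectors.
    """

    outdir: str | Path = "ricemap_run"
    scene: SceneConfig | None = None
    # real-data mode
    pre_path: str | Path | None = None
    post_path: str | Path | None = None
    rice_samples_path: str | Path | None = None
    edge_samples_path: str | Path | None = None
    truth_path: str | Path | None = None
    # band order inside the 3-band rasters
    band_order: tuple[str, str, str] = ("green", "red", "nir")
    # harvest model stage (advisory when real image dates are fixed)
    harvest_samples: pd.DataFrame | str | Path | None = None
    site_latitude: float | None = None
    site_altitude: float | None = None
    # calibration / extraction / validation parameters
    buffer_depth: float = 10.0
    edge_buffer_width: float = 2.0
    k_sigma: float = 3.0
    remove_edges: bool = True
    n_rice_points: int = 100
    n_other_points: int = 200
    seed: int = 0
    resume: bool = False

    def __post_init__(self) -> None:
        real = self.pre_path is not None or self.post_path is not None
        if real and self.scene is not None:
            raise ValueError("supply either a simulation config or real inputs, not both")
        if real and (self.pre_path is None or self.post_path is None):
            raise ValueError("real-data mode needs both pre_path and post_path")
        if not real and self.scene is None:
            self.scene = SceneConfig(seed=self.seed)

    def config_hash(self) -> str:
        d = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _load_bands(path, order):
    from .raster import read_bands

    grids = read_bands(path)
    if len(grids) < 3:
        raise ValueError(f"{path}: expected a 3-band raster, found {len(grids)} band(s)")
    return dict(zip(order, grids[:3]))


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run report dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    t_start = time.time()

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            report["stages"][name] = {"seconds": round(time.time() - t0, 3)}
            return result
        return wrap

    # -- stage: inputs (simulate or load) ------------------------------------
    def _inputs():
        if config.scene is not None:
            scene = generate_scene(config.scene)
            write_raster(scene.pre["green"], out / "pre.tif",
                         bands=[scene.pre["red"], scene.pre["nir"]])
            write_raster(scene.post["green"], out / "post.tif",
                         bands=[scene.post["red"], scene.post["nir"]])
            write_raster(scene.truth, out / "truth.tif")
            write_raster(scene.edge_truth, out / "edge_truth.tif")
            write_vector(out / "rice_samples.geojson", scene.rice_sample_polygons,
                         crs=scene.config.crs)
            write_vector(out / "edge_samples.geojson", scene.water_edge_sample_lines,
                         crs=scene.config.crs)
            return (scene.pre, scene.post, scene.rice_sample_polygons,
                    scene.water_edge_sample_lines, scene.truth_rice)
        pre = _load_bands(config.pre_path, config.band_order)
        post = _load_bands(config.post_path, config.band_order)
        if config.rice_samples_path is None or config.edge_samples_path is None:
            raise ValueError("real-data mode needs rice_samples_path and edge_samples_path")
        rice_polys = list(read_vector(config.rice_samples_path))
        edge_lines = list(read_vector(config.edge_samples_path))
        truth_rice = read_raster(config.truth_path) if config.truth_path else None
        return pre, post, rice_polys, edge_lines, truth_rice

    pre, post, rice_polys, edge_lines, truth_rice = stage("inputs")(_inputs)

    # -- stage: harvest window (advisory for fixed acquisitions) -------------
    def _harvest():
        hs = config.harvest_samples
        if hs is None:
            return None
        df = pd.read_csv(hs) if isinstance(hs, (str, Path)) else hs
        fit = fit_harvest_model(df)
        fit.save(out / "harvest_model.json")
        entry = {"see": fit.see, "r2": fit.r2, "coef_lat": fit.coef_lat,
                 "coef_alt": fit.coef_alt, "intercept": fit.intercept, "n": fit.n}
        if config.site_latitude is not None and config.site_altitude is not None:
            w = fit.predict_window(config.site_latitude, config.site_altitude)
            entry["window"] = {
                "y_center": w.y_center, "y_low": w.y_low, "y_high": w.y_high,
                "date_low": w.date_low.isoformat(), "date_high": w.date_high.isoformat(),
            }
        return entry

    harvest_entry = stage("harvest_model")(_harvest)
    if harvest_entry:
        report["harvest_model"] = harvest_entry

    # -- stage: indices -------------------------------------------------------
    def _indices():
        paths = {k: out / f"{k}.tif" for k in ("ndvi_t1", "ndvi_t2", "diff", "ndwi_t1")}
        if config.resume and all(p.exists() for p in paths.values()):
            logger.info("indices stage: reusing persisted rasters")
            return {k: read_raster(p) for k, p in paths.items()}
        g = {
            "ndvi_t1": compute_ndvi(pre["nir"], pre["red"]),
            "ndvi_t2": compute_ndvi(post["nir"], post["red"]),
            "ndwi_t1": compute_ndwi(pre["green"], pre["nir"]),
        }
        g["diff"] = compute_diff(g["ndvi_t1"], g["ndvi_t2"])
        for k, p in paths.items():
            write_raster(g[k], p)
        return g

    idx = stage("indices")(_indices)

    # -- stage: calibration ----------------------------------------------------
    def _calibrate():
        thr = calibrate_diff_threshold(idx["diff"], rice_polys,
                                       buffer_depth=config.buffer_depth,
                                       k_sigma=config.k_sigma)
        rng = calibrate_water_edge_range(idx["ndwi_t1"], edge_lines,
                                         buffer_width=config.edge_buffer_width,
                                         k_sigma=config.k_sigma)
        (out / "thresholds.json").write_text(json.dumps(thr.to_dict(), indent=1))
        (out / "water_edge_range.json").write_text(json.dumps(rng.to_dict(), indent=1))
        return thr, rng

    thresholds, edge_range = stage("calibration")(_calibrate)
    report["calibration"] = {
        "boundary_threshold": thresholds.boundary_threshold,
        "interior_threshold": thresholds.interior_threshold,
        "water_edge_low": edge_range.low,
        "water_edge_high": edge_range.high,
        "k_sigma": config.k_sigma,
    }

    # -- stage: extraction -------------------------------------------------------
    def _extract():
        initial = extract_initial(idx["diff"], thresholds.operational)
        write_raster(initial.mask, out / "rice_mask_initial.tif")
        final = initial
        if config.remove_edges:
            final = remove_water_edge(initial, idx["ndwi_t1"], edge_range)
        write_raster(final.mask, out / "rice_mask.tif")
        return initial, final

    initial_mask, final_mask = stage("extraction")(_extract)
    pixel_counts = {
        "valid_diff_pixels": int(idx["diff"].valid_mask().sum()),
        "n_initial_pixels": final_mask.n_initial_pixels,
        "n_removed_edge_pixels": final_mask.n_removed_edge_pixels,
        "removed_fraction": final_mask.removed_fraction,
    }
    scene_area_km2 = (idx["diff"].valid_mask().sum() * idx["diff"].pixel_area) / 1e6
    summary = area_stats(final_mask, study_area_km2=scene_area_km2)
    report["extraction"] = {
        **pixel_counts,
        "area_km2": summary.area_km2,
        "area_fraction_of_study_area": summary.fraction_of_study_area,
        "threshold_used": final_mask.threshold_used,
    }

    # -- stage: validation ---------------------------------------------------------
    def _validate():
        if truth_rice is None:
            logger.info("no truth raster; skipping accuracy assessment")
            return None
        pts = stratified_sample(final_mask, config.n_rice_points,
                                config.n_other_points, seed=config.seed,
                                valid=idx["diff"])
        pts = assign_truth(pts, truth_rice)
        write_vector(
            out / "validation_points.geojson",
            [Point(p.x, p.y) for p in pts],
            properties=[{"predicted": p.predicted, "truth": p.truth} for p in pts],
            crs=final_mask.mask.crs,
        )
        cm = ConfusionMatrix.from_points(pts)
        (out / "confusion_matrix.txt").write_text(cm.to_table().to_string() + "\n" + cm.summary() + "\n")
        return accuracy_metrics(cm)

    metrics = stage("validation")(_validate)
    if metrics is not None:
        report["accuracy"] = metrics

    report["total_seconds"] = round(time.time() - t_start, 3)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
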