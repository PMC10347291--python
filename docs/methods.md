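# Methods

## Harvest-period model

Rice harvest timing in hilly subtropical terrain is driven mainly by
latitude (growing-season insolation) and altitude (temperature lapse). The
model is an ordinary-least-squares plane

    y = b_lat · latitude + b_alt · altitude + b_0

with `y` a continuous day index anchored so `y = 1` corresponds to
1 August; values ≤ 0 roll back into July and values > 31 into September —
continuous day arithmetic is the only consistent extension of the anchor.
Predictor relevance is screened by first-order partial correlation
(`r_xy·z` with the other predictor as control; two-sided p-value from
`t = r√((n−3)/(1−r²))` on n−3 df). Assumptions are the usual OLS ones:
linear mean structure, homoscedastic independent residuals. Fitting needs
n ≥ 4 and a full-rank design; a constant altitude or latitude column is
rejected rather than silently absorbed.

The acquisition window is `y ± k·SEE` with k = 3 by default (≈ 99.7%
coverage under normal residuals). SEE is the regression standard error of
the estimate, `√(SSE/(n − p − 1))` with p = 2 — the denominator convention
of classic statistical packages; descriptive SDs elsewhere use n − 1.
Rounding to whole days is half-up and happens only at the calendar-mapping
step; all intermediate arithmetic stays floating point. Per-coefficient
p-values are reported but never used as an automatic gate.

## Indices and extraction

NDVI `(NIR−R)/(NIR+R)` and NDWI `(Green−NIR)/(Green+NIR)` are the same
normalized-difference functional with swapped band roles. A zero denominator
yields nodata (NaN), never 0, because 0 is a meaningful index value. Integer
digital-number rasters are rescaled by 1/10000 (the Sentinel-2 convention)
unless another scale is given.

`DiffNDVI = NDVI_pre − NDVI_post`. The rice mask is `DiffNDVI > a`
(strict inequality — "greater than", ties excluded). The threshold `a` is
`mean − 3σ` of DiffNDVI pooled over the boundary rings of the rice sample
polygons; the interior threshold is computed and reported for audit but not
applied. Pooling across samples (rather than averaging per-sample
statistics) is the default because a single operational threshold should
weight every calibration pixel equally; the per-sample alternative is
available behind a flag.

The water-edge interval is `mean ± 3σ` of pre-harvest NDWI pooled over 2 m
two-sided ribbons around the water-edge sample lines, treated as closed on
both ends (at float precision the distinction is immaterial; closed is safer
for suppression). Removal clears mask pixels inside the interval; it is
idempotent, and the NDWI used is the pre-harvest one (mixed pixels are
shore-like on that date), with the post-harvest alternative selectable.
No morphological cleanup (sieve/opening) is applied.

## Geometry-to-pixel conventions

* Pixel membership is center-in-polygon: a 10 m inward buffer selects
  exactly one ring of 10 m pixels, and the selection is deterministic.
* Inward splitting: interior = polygon eroded by the buffer depth, boundary
  = polygon minus interior; erosion to emptiness makes the whole polygon
  boundary. Areas are conserved to 1e-6 relative tolerance.
* Edge ribbons use flat caps and include both sides of the line. A 2 m
  ribbon on 10 m pixels is sub-pixel and can miss every center; only when
  the strict selection is empty is the ribbon dilated to one pixel diagonal
  (logged). Generated sample lines pass through pixel centers, so the strict
  path is the normal one.
* All metric operations require a projected CRS; buffering in geographic
  degrees is refused.
* Rasters are north-up GeoTIFFs (row 0 at the north edge); nodata follows
  the GDAL tag convention.

## Validation

Validation points are stratified by *predicted* class (the mask layers),
uniform without replacement within each stratum, deterministic per seed.
The confusion matrix is stored rows = truth × columns = predicted;
`to_table()` emits the conventional report layout (rows = classification,
columns = reference) whose margins give user accuracy per predicted class
and producer accuracy per truth class. Kappa is
`(p_o − p_e)/(1 − p_e)` with `p_e = Σ row_i · col_i / N²`; a single-cell
matrix has `p_e = 1` and kappa is reported as NaN. Display rounding is 2 dp;
machine-readable reports keep full precision.

## Synthetic scenes

The generator emulates the data the method consumes, not radiative
transfer. A 240 × 240 px, 10 m scene is banded north to south —
construction, dry land, rice, forest/grass — with a water body at the
south edge behind a sinusoidal shoreline. Per class it holds noise-free
index targets (pre-harvest NDVI, NDVI drop, NDWI) and derives band
reflectances by inverting the index definitions at a class-specific red-band
base value:

| class        | pre-NDVI | drop | NDWI  | red base |
|--------------|---------:|-----:|------:|---------:|
| rice         | 0.80     | 0.33 | −0.60 | 0.10     |
| dry land     | 0.78     | 0.09 | −0.40 | 0.10     |
| water        | −0.30    | 0.04 | +0.55 | 0.20     |
| construction | 0.25     | 0.03 | −0.15 | 0.18     |
| forest/grass | 0.85     | 0.08 | −0.55 | 0.05     |

The drops are the observed per-class values the method exploits; the NDVI
levels follow the qualitative class ranking (forest > rice ≈ dry land >
construction > water). Red-base values were chosen once, by error
propagation, so that 0.01-SD reflectance noise yields a DiffNDVI sigma of
roughly 0.04 over rice — placing the calibrated `mean − 3σ` boundary
threshold near 0.20, comfortably separating the 0.33 rice drop from the
0.09 dry-land drop. Water gets a relatively bright base (turbid water)
because normalized differences of very dark pixels amplify noise
unrealistically. Rice NDWI (−0.60) sits far outside the mixed-pixel NDWI
(≈ −0.14 for a 50/50 forest/water blend), so edge removal cannot eat true
rice.

Gaussian noise (default SD 0.01) is added to reflectance per band and date,
not to indices, which induces realistic heteroscedastic index noise. The
shoreline advances landward by 1 pixel between dates; the vacated ribbon is
a 50/50 linear reflectance blend of its land class and water at t1 and pure
water at t2 — the simplest model that produces the shore-at-t1/water-at-t2
false-positive mechanism. 33 five-by-five-pixel rice sample polygons are
laid out inside the contiguous rice band; 20 water-edge sample lines follow
runs of the mixed ribbon through pixel centers. A scatter fraction (default
1% of the dry-land band) adds isolated single-pixel rice fields. Harvest
surveys draw 32 uniform (latitude, altitude) points over 28.5–31.5° and
150–1200 m and add N(0, 2.749²) day noise around the plane
`8.077·lat + 0.056·alt − 245.040`.

What the scenes do **not** emulate: atmospheric effects, clouds and shadows,
within-class texture and spatial autocorrelation, mixed pixels at non-water
class boundaries, topographic illumination, and sensor PSF. Passing tests
therefore demonstrate the correctness and internal consistency of the
procedure — calibration arithmetic, the edge-effect mechanism and its
removal, accuracy bookkeeping — not field-scale accuracy on real imagery,
where boundary mixing of all classes and phenological variability will
lower accuracy.

## Numerical choices and limitations

* Sample SD uses n − 1 throughout; a single-pixel zone reports SD 0.
* Threshold ties are excluded (strict `>`); interval membership is closed.
* Reflectance inversion clips bands into (0, 1] and errors if clipping would
  shift a recomputed index by more than 1e-6 (infeasible target pair).
* Scene generation, sampling and surveys are all driven by
  `numpy.random.default_rng(seed)`; identical seeds give bit-identical
  scenes and reports.
* Default problem sizes (240 × 240 px scenes; 200-replicate recovery runs)
  keep the full suite and pipeline runs in the seconds range; all sizes are
  configuration, not constants.
* GeoTIFF georeferencing covers north-up affine transforms and EPSG codes
  only; shear/rotation and non-EPSG CRSs are out of scope, as are
  reprojection and resampling. Vector I/O is GeoJSON; convert Shapefiles
  upstream.
* The interior threshold plays no role in extraction; it is reported because
  the calibration naturally produces it and it documents the boundary/
  interior contrast of the samples.
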