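# ricemap

Paddy-rice field extraction from a pre/post-harvest pair of Sentinel-2-like
images by NDVI temporal differencing, with NDWI-based removal of shoreline
false positives and a stratified confusion-matrix accuracy assessment.

**Who it is for:** remote-sensing practitioners mapping rice in hilly
subtropical terrain from two well-timed 10 m acquisitions, and anyone who
wants a fully reproducible, synthetic-scene testbed for the method.

## The method

Harvested rice shows the sharpest vegetation-index drop of any land cover
between a pre-harvest and a post-harvest date. The workflow:

1. **Harvest window.** The harvest day index `y` (anchored so `y = 1` means
   1 August) is regressed on latitude `X1` (degrees) and altitude `X2` (m):
   `y = b1·X1 + b2·X2 + b0`, fitted by OLS after partial-correlation
   screening of the two predictors. The acquisition window is
   `y ± 3·SEE`, where SEE = √(SSE/(n−3)) is the regression standard error
   of the estimate; endpoints are rounded half-up to whole days.
2. **Differencing.** `NDVI = (NIR − R)/(NIR + R)` on each date;
   `DiffNDVI = NDVI_t1 − NDVI_t2`.
3. **Threshold calibration.** Each rice sample polygon is split into a 10 m
   boundary ring (mixed pixels) and its interior; pixels are pooled across
   samples and the extraction threshold is `mean − 3σ` of the boundary zone.
   A pixel is rice when `DiffNDVI > a` (strict).
4. **Water-edge cleanup.** Where the water boundary moved between dates,
   shore-mixed-at-t1 / water-at-t2 pixels mimic the rice drop. 2 m ribbons
   around water-edge sample lines calibrate an NDWI interval
   `mean ± 3σ` on the pre-harvest image; mask pixels whose NDWI falls in the
   closed interval are removed.
5. **Validation.** Stratified random points (default 100 on the rice layer,
   200 off it) against truth labels give user/producer/overall accuracy and
   Cohen's kappa `κ = (p_o − p_e)/(1 − p_e)`.

A synthetic-scene generator produces the full input set with known ground
truth: five land-cover classes with prescribed NDVI drops
(rice 0.33, dry land 0.09, water 0.04, construction 0.03, forest/grass 0.08),
a shifting sinusoidal shoreline that creates the water-edge effect, sample
polygons/lines, and 32-point harvest surveys drawn from the plane
`y = 8.077·X1 + 0.056·X2 − 245.040` with residual SD 2.749 days.

## Worked example

```sh
ricemap run --seed 1 -o run1
```

simulates a 240 × 240 px (10 m) scene, fits the harvest model on a generated
32-point survey, computes the indices, calibrates, extracts, cleans and
validates. The printed report (abridged):

```
harvest_model:  see 2.278, r2 0.985, window 2019-08-02 .. 2019-08-16
calibration:    boundary_threshold 0.1966   interior_threshold 0.1882
                water_edge interval (-0.2064, -0.0753)
extraction:     n_initial_pixels 19714   n_removed_edge_pixels 238
                removed_fraction 0.0121  area_km2 1.9476
accuracy:       overall_accuracy 0.990   kappa 0.977
```

Reading it: the calibrated boundary threshold (`mean − 3σ` of DiffNDVI over
the 33 sample-polygon boundary rings) lands near 0.20 — well below the rice
drop of 0.33 and above every other class's drop. 19,714 pixels exceed it;
238 of them (1.2%) are shoreline mixed pixels whose pre-harvest NDWI falls
inside the calibrated water-edge interval and are removed. Scored against
the generator's truth at 300 stratified points, the final mask reaches 99%
overall accuracy with κ = 0.98.

Every stage is also available on its own (`ricemap simulate`,
`ricemap indices ndvi|ndwi|diff`, `ricemap harvest fit|predict|map`,
`ricemap calibrate diff|wateredge`, `ricemap extract`,
`ricemap validate sample|score`), and as library functions
(`ricemap.generate_scene`, `ricemap.HarvestModel(...).fit()`,
`ricemap.calibrate_diff_threshold`, ...).

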