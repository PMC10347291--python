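"""Harvest-period regression, windows, and the calendar mapping."""

import datetime

import numpy as np
import pytest

from ricemap import HarvestFit, HarvestModel, fit_harvest_model, partial_correlation
from ricemap.harvest import day_index_to_date, round_half_up
from ricemap.synthetic import generate_harvest_samples

from conftest import make_grid

# published plane used as synthetic truth throughout
COEF_LAT, COEF_ALT, INTERCEPT, SEE = 8.077, 0.056, -245.040, 2.749


def residual_partial_corr(x, y, z):
    """Independent oracle: correlate OLS residuals of x|z and y|z."""
    x, y, z = (np.asarray(v, float) for v in (x, y, z))
    Z = np.column_stack([np.ones_like(z), z])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    return np.corrcoef(rx, ry)[0, 1]


class TestPartialCorrelation:
    def test_uncorrelated_control_leaves_r_unchanged(self):
        rng = np.random.default_rng(3)
        n = 4000
        x = rng.normal(size=n)
        y = 0.9 * x + rng.normal(scale=np.sqrt(1 - 0.81), size=n)
        z = rng.normal(size=n)  # independent of both
        r, p = partial_correlation(x, y, z)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.01)
        assert p < 1e-10

    def test_matches_residual_oracle_on_fixed_six_points(self):
        x = [1.0, 2.0, 4.0, 4.5, 7.0, 9.0]
        y = [2.0, 1.0, 5.0, 6.0, 6.5, 10.0]
        z = [0.5, 1.5, 1.0, 3.0, 2.5, 4.0]
        r, _ = partial_correlation(x, y, z)
        assert r == pytest.approx(residual_partial_corr(x, y, z), abs=1e-10)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(11)
        x, y, z = rng.normal(size=(3, 50))
        r_xy, _ = partial_correlation(x, y, z)
        r_yx, _ = partial_correlation(y, x, z)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        r_scaled, _ = partial_correlation(3.0 * x - 7.0, 0.5 * y + 2.0, -2.0 * z + 1.0)
        assert r_scaled == pytest.approx(r_xy, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="constant"):
            partial_correlation([1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1])
        z = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(2 * z + 1, [1.0, 3.0, 2.0, 5.0], z)
        with pytest.raises(ValueError, match="at least 4"):
            partial_correlation([1, 2, 3], [3, 1, 2], [2, 3, 1])


class TestFit:
    def test_exact_plane_recovery(self):
        df = generate_harvest_samples(n=32, noise_sd=0.0, seed=5)
        fit = fit_harvest_model(df)
        assert fit.coef_lat == pytest.approx(COEF_LAT, abs=1e-8)
        assert fit.coef_alt == pytest.approx(COEF_ALT, abs=1e-8)
        assert fit.intercept == pytest.approx(INTERCEPT, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.see == pytest.approx(0.0, abs=1e-7)

    def test_four_points_match_normal_equations(self):
        lat = np.array([29.0, 30.0, 31.0, 29.5])
        alt = np.array([200.0, 800.0, 400.0, 650.0])
        y = np.array([5.0, 14.0, 21.0, 9.0])
        X = np.column_stack([np.ones(4), lat, alt])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fit = HarvestModel(y, lat, alt).fit()
        assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
        assert fit.coef_lat == pytest.approx(beta[1], rel=1e-10)
        assert fit.coef_alt == pytest.approx(beta[2], rel=1e-10)
        # SEE on n=4, p=2: sqrt(SSE / 1)
        sse = float(((y - X @ beta) ** 2).sum())
        assert fit.see == pytest.approx(np.sqrt(sse), rel=1e-8)

    def test_duplicate_locations_with_different_days(self):
        lat = np.array([29.0, 29.0, 30.0, 31.0, 30.5])
        alt = np.array([200.0, 200.0, 500.0, 300.0, 800.0])
        y = np.array([4.0, 6.0, 12.0, 20.0, 18.0])
        fit = HarvestModel(y, lat, alt).fit()
        assert fit.see > 0

    def test_rank_deficient_design(self):
        lat = np.array([29.0, 30.0, 31.0, 32.0])
        alt = np.full(4, 500.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            HarvestModel(np.arange(4.0), lat, alt).fit()

    def test_save_load_roundtrip(self, tmp_path):
        fit = fit_harvest_model(generate_harvest_samples(seed=2))
        fit.save(tmp_path / "m.json")
        back = HarvestFit.load(tmp_path / "m.json")
        assert back.coef_lat == fit.coef_lat and back.see == fit.see


class TestWindow:
    def test_worked_example_first_to_eighteenth_august(self):
        fit = HarvestFit.from_params(COEF_LAT, COEF_ALT, INTERCEPT, SEE)
        w = fit.predict_window(29.82, 242.81, k_sigma=3)
        assert w.y_center == pytest.approx(9.41, abs=0.005)
        assert w.margin == pytest.approx(8.247, abs=1e-12)
        assert w.date_low == datetime.date(2019, 8, 1)
        assert w.date_high == datetime.date(2019, 8, 18)

    def test_window_width_is_2k_see(self):
        fit = HarvestFit.from_params(COEF_LAT, COEF_ALT, INTERCEPT, SEE)
        for k in (0.5, 1, 2, 3, 5):
            w = fit.predict_window(30.0, 400.0, k_sigma=k)
            assert w.y_high - w.y_low == pytest.approx(2 * k * SEE)

    def test_zero_k_collapses_to_center(self):
        fit = HarvestFit.from_params(COEF_LAT, COEF_ALT, INTERCEPT, SEE)
        w = fit.predict_window(29.82, 242.81, k_sigma=0)
        assert w.date_low == w.date_high

    def test_calendar_anchor_and_rollover(self):
        assert day_index_to_date(1) == datetime.date(2019, 8, 1)
        assert day_index_to_date(0) == datetime.date(2019, 7, 31)
        assert day_index_to_date(32) == datetime.date(2019, 9, 1)
        assert round_half_up(1.17) == 1
        assert round_half_up(17.66) == 18
        assert round_half_up(2.5) == 3


class TestMap:
    def test_constant_inputs_give_constant_map(self):
        fit = HarvestFit.from_params(COEF_LAT, COEF_ALT, INTERCEPT, SEE)
        dem = make_grid(np.full((4, 4), 242.81))
        lat = dem.like(np.full((4, 4), 29.82))
        out = fit.map_harvest_period(dem, lat)
        assert np.allclose(out.values, fit.predict(29.82, 242.81))

    def test_sensitivity_to_altitude_and_latitude(self):
        fit = HarvestFit.from_params(COEF_LAT, COEF_ALT, INTERCEPT, SEE)
        dem = make_grid(np.full((2, 2), 300.0))
        lat = dem.like(np.full((2, 2), 30.0))
        base = fit.map_harvest_period(dem, lat).values
        up100 = fit.map_harvest_period(dem.like(dem.values + 100.0), lat).values
        assert np.allclose(up100 - base, 5.6)
        lat1 = fit.map_harvest_period(dem, lat.like(lat.values + 1.0)).values
        assert np.allclose(lat1 - base, 8.077)

    def test_superposition(self):
        fit = HarvestFit.from_params(COEF_LAT, COEF_ALT, INTERCEPT, SEE)
        rng = np.random.default_rng(4)
        dem_v, lat_v = rng.uniform(100, 1000, (3, 3)), rng.uniform(28, 32, (3, 3))
        dem = make_grid(dem_v)
        out = fit.map_harvest_period(dem, dem.like(lat_v)).values
        expected = COEF_LAT * lat_v + COEF_ALT * dem_v + INTERCEPT
        assert np.allclose(out, expected)

    def test_nodata_propagates_from_dem(self):
        fit = HarvestFit.from_params(COEF_LAT, COEF_ALT, INTERCEPT, SEE)
        dem = make_grid(np.array([[100.0, -9999.0]]), nodata=-9999.0)
        out = fit.map_harvest_period(dem, dem.like(np.full((1, 2), 30.0)))
        assert np.isfinite(out.values[0, 0]) and np.isnan(out.values[0, 1])

    def test_latitude_from_geographic_transform(self):
        fit = HarvestFit.from_params(COEF_LAT, COEF_ALT, INTERCEPT, SEE)
        from ricemap import Grid, GridTransform

        dem = Grid(np.full((2, 2), 500.0),
                   GridTransform.from_origin(106.0, 30.0, 0.01), crs="EPSG:4326")
        out = fit.map_harvest_period(dem)
        # row 0 centers at latitude 29.995, row 1 at 29.985
        assert out.values[0, 0] == pytest.approx(fit.predict(29.995, 500.0))
        assert out.values[1, 0] == pytest.approx(fit.predict(29.985, 500.0))


class TestParameterRecovery:
    def test_noisy_fits_cover_truth_and_see_band(self):
        """n = 32, noise SD 2.749: 95% CIs cover each true coefficient in
        >= 90% of replicates, and the refitted SEE stays in the chi-square
        band for an SD at 29 df in nearly all of them."""
        n_rep = 200
        hits = np.zeros(3)
        see_in_band = 0
        for s in range(n_rep):
            df = generate_harvest_samples(n=32, noise_sd=SEE, seed=s)
            fit = fit_harvest_model(df)
            ci = fit.conf_int(0.05)
            for i, (name, truth) in enumerate(
                [("intercept", INTERCEPT), ("latitude", COEF_LAT), ("altitude", COEF_ALT)]
            ):
                lo, hi = ci[name]
                hits[i] += lo <= truth <= hi
            see_in_band += 1.9 <= fit.see <= 3.7
        assert (hits / n_rep >= 0.90).all()
        assert see_in_band / n_rep >= 0.95
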