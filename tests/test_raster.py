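"""Raster I/O and geometry-to-pixel machinery."""

import numpy as np
import pytest
import shapely
from shapely.geometry import LineString, Polygon, box

from ricemap import (Grid, GridTransform, inward_buffer_split, pixels_in_zone,
                     read_raster, read_vector, two_sided_buffer, write_raster,
                     write_vector)
from ricemap.raster import pixels_in_edge_ribbon

from conftest import make_grid


class TestRasterIO:
    def test_roundtrip_identity(self, tmp_path):
        g = make_grid(np.arange(16, dtype=np.float64).reshape(4, 4) / 7.0,
                      origin=(1000.0, 2000.0), nodata=-9999.0)
        p = write_raster(g, tmp_path / "g.tif")
        g2 = read_raster(p)
        np.testing.assert_array_equal(g.values, g2.values)
        assert g2.transform == g.transform
        assert g2.crs == g.crs
        assert g2.nodata == g.nodata

    def test_integer_mask_roundtrip_bit_faithful(self, tmp_path):
        g = make_grid(np.array([[0, 1], [1, 0]], dtype=np.uint8))
        g2 = read_raster(write_raster(g, tmp_path / "m.tif"))
        assert g2.values.dtype == np.uint8
        np.testing.assert_array_equal(g.values, g2.values)

    def test_multiband_band_selection(self, tmp_path):
        base = make_grid(np.full((3, 3), 0.1))
        b2 = base.like(np.full((3, 3), 0.2))
        b3 = base.like(np.full((3, 3), 0.3))
        p = write_raster(base, tmp_path / "mb.tif", bands=[b2, b3])
        assert np.allclose(read_raster(p, band=3).values, 0.3)
        assert np.allclose(read_raster(p, band=1).values, 0.1)
        with pytest.raises(IndexError, match="band 4"):
            read_raster(p, band=4)

    def test_missing_georeferencing_is_an_error(self, tmp_path):
        import tifffile

        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, np.zeros((2, 2), dtype=np.float32))
        with pytest.raises(ValueError, match="plain.tif"):
            read_raster(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_raster(tmp_path / "nope.tif")


class TestVectorIO:
    def test_geojson_roundtrip_with_properties(self, tmp_path):
        geoms = [box(0, 0, 10, 10), LineString([(0, 0), (5, 5)])]
        props = [{"kind": "rice"}, {"kind": "edge"}]
        p = write_vector(tmp_path / "v.geojson", geoms, props, crs="EPSG:32648")
        fs = read_vector(p)
        assert fs.crs == "EPSG:32648"
        assert fs.properties == props
        assert fs.geometries[0].equals(geoms[0])

    def test_shapefile_refused(self, tmp_path):
        (tmp_path / "x.shp").write_bytes(b"\x00")
        with pytest.raises(ValueError, match="GeoJSON"):
            read_vector(tmp_path / "x.shp")


class TestPixelsInZone:
    def test_full_cover(self):
        g = make_grid([[1.0, 2.0], [3.0, 4.0]])
        vals = pixels_in_zone(g, box(-1, -1, 21, 21))
        assert sorted(vals) == [1.0, 2.0, 3.0, 4.0]

    def test_left_column_by_pixel_centers(self):
        # centers of the left column sit at x = 5; the polygon covers x in [0, 10)
        g = make_grid([[1.0, 2.0], [3.0, 4.0]])
        vals = pixels_in_zone(g, box(0, 0, 9.9, 20))
        # brute-force oracle: test each center individually
        expected = []
        for r in range(2):
            for c in range(2):
                x, y = g.transform.xy(r, c)
                if shapely.contains_xy(box(0, 0, 9.9, 20), x, y):
                    expected.append(g.values[r, c])
        assert sorted(vals) == sorted(expected) == [1.0, 3.0]

    def test_disjoint_zone_empty(self):
        g = make_grid([[1.0, 2.0], [3.0, 4.0]])
        assert pixels_in_zone(g, box(100, 100, 200, 200)).size == 0

    def test_crs_mismatch(self):
        g = make_grid([[1.0]])
        with pytest.raises(ValueError, match="CRS"):
            pixels_in_zone(g, box(0, 0, 10, 10), zone_crs="EPSG:4326")

    def test_nodata_excluded(self):
        g = make_grid(np.array([[1.0, -9.0], [3.0, 4.0]]), nodata=-9.0)
        assert sorted(pixels_in_zone(g, box(-1, -1, 21, 21))) == [1.0, 3.0, 4.0]

    def test_union_additivity_for_disjoint_zones(self):
        rng = np.random.default_rng(7)
        g = make_grid(rng.normal(size=(6, 6)))
        a, b = box(0, 0, 30, 60), box(30, 0, 60, 60)
        va = pixels_in_zone(g, a)
        vb = pixels_in_zone(g, b)
        vu = pixels_in_zone(g, a.union(b))
        assert sorted(np.concatenate([va, vb])) == pytest.approx(sorted(vu))


def _rasterized_area(geom, cell=0.25):
    """Brute-force area by fine-grid pixel-center counting."""
    minx, miny, maxx, maxy = geom.bounds
    xs = np.arange(minx - cell, maxx + cell, cell) + cell / 2
    ys = np.arange(miny - cell, maxy + cell, cell) + cell / 2
    X, Y = np.meshgrid(xs, ys)
    return shapely.contains_xy(geom, X.ravel(), Y.ravel()).sum() * cell**2


class TestZoneSplit:
    def test_square_split_areas(self):
        split = inward_buffer_split(box(0, 0, 50, 50), 10)
        assert split.interior_zone.area == pytest.approx(900.0)
        assert split.boundary_zone.area == pytest.approx(1600.0)

    def test_collapse_when_too_deep(self):
        split = inward_buffer_split(box(0, 0, 15, 15), 10)
        assert split.interior_zone.is_empty
        assert split.boundary_zone.equals(box(0, 0, 15, 15))

    def test_L_shape_against_rasterization_oracle(self):
        L = Polygon([(0, 0), (60, 0), (60, 30), (30, 30), (30, 60), (0, 60)])
        split = inward_buffer_split(L, 10)
        assert split.interior_zone.area == pytest.approx(_rasterized_area(split.interior_zone), rel=0.02)
        assert split.boundary_zone.area == pytest.approx(_rasterized_area(split.boundary_zone), rel=0.02)

    @pytest.mark.parametrize("depth", [1.0, 5.0, 10.0, 24.0])
    def test_area_conservation(self, depth):
        L = Polygon([(0, 0), (60, 0), (60, 30), (30, 30), (30, 60), (0, 60)])
        split = inward_buffer_split(L, depth)
        total = split.boundary_zone.area + split.interior_zone.area
        assert total == pytest.approx(L.area, rel=1e-6)
        assert split.boundary_zone.intersection(split.interior_zone).area == pytest.approx(0.0, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            inward_buffer_split(box(0, 0, 10, 10), 0)
        bowtie = Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        with pytest.raises(ValueError):
            inward_buffer_split(bowtie, 1)


class TestTwoSidedBuffer:
    def test_straight_segment_flat_caps(self):
        ribbon = two_sided_buffer(LineString([(0, 0), (100, 0)]), 2)
        assert ribbon.area == pytest.approx(400.0)

    def test_closed_square_boundary_ribbon(self):
        ribbon = two_sided_buffer(box(0, 0, 50, 50), 2)
        # perimeter x 2w, checked against a brute-force rasterized area
        assert ribbon.area == pytest.approx(_rasterized_area(ribbon), rel=0.02)
        assert ribbon.area == pytest.approx(200 * 4, rel=0.05)

    def test_zero_width_is_an_error(self):
        with pytest.raises(ValueError):
            two_sided_buffer(LineString([(0, 0), (1, 0)]), 0)

    def test_geographic_crs_refused_for_ribbon_selection(self):
        g = Grid(np.zeros((2, 2)), GridTransform.from_origin(106.0, 30.0, 0.0001),
                 crs="EPSG:4326")
        with pytest.raises(ValueError, match="geographic"):
            pixels_in_edge_ribbon(g, LineString([(106.0, 29.999), (106.0002, 29.999)]), 2)


class TestEdgeRibbonFallback:
    def test_subpixel_ribbon_dilates_to_pixel_diagonal(self, caplog):
        # line between two pixel-center rows: the strict 2 m ribbon misses all centers
        g = make_grid(np.arange(16, dtype=float).reshape(4, 4))
        line = LineString([(0, 20), (40, 20)])  # along a pixel edge
        import logging

        with caplog.at_level(logging.WARNING, logger="ricemap.raster"):
            vals = pixels_in_edge_ribbon(g, line, 2)
        assert vals.size > 0
        assert any("dilating" in r.message for r in caplog.records)
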