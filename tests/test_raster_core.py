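"""Resampling, pixel areas and mask algebra."""

import numpy as np
import pytest

from reforest.raster_core import (
    AUTHALIC_RADIUS_M,
    Grid,
    GridGeometry,
    GridTransform,
    RasterError,
    mask_apply,
    pixel_area,
    resample,
)
from tests.conftest import geometry, make_grid


class TestResample:
    @pytest.mark.parametrize("method", ["nearest", "bilinear", "max", "mean"])
    def test_constant_field_is_invariant(self, method):
        src = make_grid(np.full((8, 8), 3.25), px=0.125)
        out = resample(src, geometry(2, 2, px=0.5), method)
        assert np.allclose(out.values, 3.25)

    def test_mean_of_2x2_block(self):
        src = make_grid(np.array([[0.0, 0.0], [1.0, 1.0]]), px=0.5)
        out = resample(src, geometry(1, 1, px=1.0), "mean")
        # rows carry slightly different spherical band weights; at 0-1 deg N
        # the plain mean 0.5 is recovered to ~1e-4 and the weighted value
        # is below it (the lower row, value 1, sits nearer the equator)
        assert out.values[0, 0] == pytest.approx(0.5, abs=1e-3)

    def test_max_of_2x2_block(self):
        src = make_grid(np.array([[0.0, 3.0], [1.0, 2.0]]), px=0.5)
        out = resample(src, geometry(1, 1, px=1.0), "max")
        assert out.values[0, 0] == 3.0

    def test_mean_aggregation_matches_block_counting_oracle(self):
        # tiny pixels at the equator: band-weight variation is O(px^2),
        # so the area-weighted mean equals count-of-ones/16 to < 1e-9
        rng = np.random.default_rng(0)
        binary = (rng.random((16, 16)) < 0.4).astype(float)
        px = 1e-4
        src = make_grid(binary, north=8 * px, px=px)
        tgt = GridGeometry(
            GridTransform(0.0, 8 * px, 4 * px, 4 * px), (4, 4)
        )
        out = resample(src, tgt, "mean")
        oracle = binary.reshape(4, 4, 4, 4).mean(axis=(1, 3))
        assert np.allclose(out.values, oracle, atol=1e-9)

    def test_mean_conserves_value_times_area(self):
        rng = np.random.default_rng(1)
        vals = rng.random((32, 32)) * 10
        src = make_grid(vals, north=60.0, px=0.25)  # high latitude: skewed areas
        tgt = geometry(8, 8, north=60.0, px=1.0)
        out = resample(src, tgt, "mean")
        fine_sum = np.sum(vals * pixel_area(src).values)
        coarse_sum = np.sum(out.values * pixel_area(Grid(out.values, tgt.transform)).values)
        assert coarse_sum == pytest.approx(fine_sum, rel=1e-9)

    def test_max_at_least_mean_for_nonnegative(self):
        rng = np.random.default_rng(2)
        src = make_grid(rng.random((16, 16)), px=0.0625)
        tgt = geometry(4, 4, px=0.25)
        mx = resample(src, tgt, "max").values
        mn = resample(src, tgt, "mean").values
        assert (mx >= mn - 1e-12).all()

    def test_nearest_round_trip_is_idempotent(self):
        rng = np.random.default_rng(3)
        src = make_grid(rng.integers(0, 5, (8, 8)).astype(float), px=0.125)
        up = resample(src, geometry(16, 16, px=0.0625), "nearest")
        back = resample(up, src.geometry, "nearest")
        assert np.array_equal(back.values, src.values)

    def test_bilinear_rejected_on_categorical(self):
        src = make_grid(np.zeros((4, 4), dtype=np.int16), px=0.25, categorical=True)
        with pytest.raises(RasterError, match="categorical"):
            resample(src, geometry(2, 2, px=0.5), "bilinear")

    def test_disjoint_geometries_rejected(self):
        src = make_grid(np.zeros((4, 4)), px=0.25)
        far = GridGeometry(GridTransform(50.0, 1.0, 0.25, 0.25), (4, 4))
        with pytest.raises(RasterError, match="overlap"):
            resample(src, far, "mean")

    def test_aggregation_ignores_nodata_and_propagates_when_all_missing(self):
        vals = np.array([[1.0, -9.0], [-9.0, -9.0], [-9.0, -9.0], [-9.0, -9.0]])
        src = make_grid(vals, px=0.5, nodata=-9.0)
        # 4x2 source -> 2x1 target: top block has one valid cell, bottom none
        tgt = GridGeometry(GridTransform(0.0, 1.0, 1.0, 1.0), (2, 1))
        out = resample(src, tgt, "mean")
        assert out.values[0, 0] == pytest.approx(1.0)
        assert np.isnan(out.values[1, 0])


class TestPixelArea:
    def test_mirror_symmetry_about_equator(self):
        north = pixel_area(make_grid(np.zeros((1, 1)), north=31.0, px=1.0))
        south = pixel_area(make_grid(np.zeros((1, 1)), north=-30.0, px=1.0))
        assert north.values[0, 0] == pytest.approx(south.values[0, 0], rel=1e-12)

    def test_band_ratio_matches_closed_form(self):
        hi = pixel_area(make_grid(np.zeros((1, 1)), north=61.0, px=1.0)).values[0, 0]
        lo = pixel_area(make_grid(np.zeros((1, 1)), north=1.0, px=1.0)).values[0, 0]
        expected = (np.sin(np.radians(61)) - np.sin(np.radians(60))) / (
            np.sin(np.radians(1)) - np.sin(np.radians(0))
        )
        assert hi / lo == pytest.approx(expected, rel=1e-12)

    def test_equator_cell_matches_numerical_integration(self):
        cell = pixel_area(make_grid(np.zeros((1, 1)), north=1.0, px=1.0)).values[0, 0]
        # independent oracle: integrate R^2 cos(phi) dphi dlambda numerically
        from scipy.integrate import quad

        integral, _ = quad(lambda phi: np.cos(phi), 0.0, np.radians(1.0))
        expected_ha = AUTHALIC_RADIUS_M**2 * np.radians(1.0) * integral / 1e4
        assert cell == pytest.approx(expected_ha, rel=1e-10)

    def test_full_sphere_of_one_degree_cells(self):
        grid = Grid(np.zeros((180, 360)), GridTransform(-180.0, 90.0, 1.0, 1.0))
        total_m2 = np.sum(pixel_area(grid).values) * 1e4
        sphere = 4 * np.pi * AUTHALIC_RADIUS_M**2
        assert total_m2 == pytest.approx(sphere, rel=1e-9)

    def test_monotone_decrease_toward_pole(self):
        grid = Grid(np.zeros((90, 1)), GridTransform(0.0, 90.0, 1.0, 1.0))
        col = pixel_area(grid).values[:, 0]
        assert (np.diff(col) > 0).all()  # rows go from pole toward equator

    def test_latitudes_beyond_pole_rejected(self):
        grid = Grid(np.zeros((2, 2)), GridTransform(0.0, 91.0, 1.0, 1.0))
        with pytest.raises(RasterError, match="latitude"):
            pixel_area(grid)


class TestMaskApply:
    def test_all_ones_is_identity(self):
        vals = make_grid(np.arange(16.0).reshape(4, 4), px=0.25)
        mask = make_grid(np.ones((4, 4), dtype=np.uint8), px=0.25)
        out = mask_apply(vals, mask, outside=0.0)
        assert np.array_equal(out.values, vals.values)

    def test_all_zeros_gives_outside_value(self):
        vals = make_grid(np.arange(16.0).reshape(4, 4), px=0.25)
        mask = make_grid(np.zeros((4, 4), dtype=np.uint8), px=0.25)
        out = mask_apply(vals, mask, outside=0.0)
        assert (out.values == 0).all()

    def test_checkerboard_alternation_cellwise(self):
        vals = make_grid(np.full((4, 4), 7.0), px=0.25)
        board = np.indices((4, 4)).sum(axis=0) % 2
        mask = make_grid(board.astype(np.uint8), px=0.25)
        out = mask_apply(vals, mask, outside=-1.0)
        expected = np.where(board == 1, 7.0, -1.0)
        assert np.array_equal(out.values, expected)

    def test_misaligned_rejected(self):
        vals = make_grid(np.zeros((4, 4)), px=0.25)
        mask = make_grid(np.ones((4, 4), dtype=np.uint8), px=0.2)
        with pytest.raises(RasterError):
            mask_apply(vals, mask)

    def test_nodata_preserved(self):
        vals = make_grid(np.array([[np.nan, 2.0], [3.0, 4.0]]), px=0.5, nodata=np.nan)
        mask = make_grid(np.zeros((2, 2), dtype=np.uint8), px=0.5)
        out = mask_apply(vals, mask, outside=9.0)
        assert np.isnan(out.values[0, 0])
        assert out.values[1, 1] == 9.0


def test_geotiff_round_trip(tmp_path):
    from reforest.geotiff import read_geotiff, write_geotiff

    rng = np.random.default_rng(5)
    g = make_grid(rng.random((6, 9)), px=0.125, res_class="mid", nodata=np.nan)
    g.values[0, 0] = np.nan
    write_geotiff(tmp_path / "g.tif", g)
    back = read_geotiff(tmp_path / "g.tif")
    assert np.array_equal(back.values, g.values, equal_nan=True)
    assert back.res_class == "mid"
    t, bt = g.transform, back.transform
    assert (t.origin_lon, t.origin_lat, t.px_width, t.px_height) == (
        bt.origin_lon, bt.origin_lat, bt.px_width, bt.px_height
    )
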