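"""Signed built-edge distance, slope, lights composite, feature distance, stacks."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from popgrid import (
    GridRaster,
    build_stack,
    composite_lights,
    distance_to_features,
    signed_distance_to_edge,
    slope_from_elevation,
)
from popgrid.covariates import CovariateError, CovariateStack


def _binary(mask, ps=100.0):
    mask = np.asarray(mask, dtype=np.int32)
    return GridRaster(mask, 0, mask.shape[0] * ps, ps)


def brute_force_signed_distance(mask, ps):
    """All-pairs nearest-cell oracle for the signed edge distance."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.indices(mask.shape)
    coords = np.column_stack([rows.ravel(), cols.ravel()]) * ps
    built = coords[mask.ravel()]
    open_ = coords[~mask.ravel()]
    out = np.empty(mask.size)
    out[mask.ravel()] = -cdist(built, open_).min(axis=1)
    out[~mask.ravel()] = cdist(open_, built).min(axis=1)
    return out.reshape(mask.shape)


class TestSignedDistance:
    def test_single_built_pixel_neighbors(self):
        mask = np.zeros((5, 5), dtype=int)
        mask[2, 2] = 1
        d = signed_distance_to_edge(_binary(mask)).values
        assert d[2, 2] == pytest.approx(-100.0)
        assert d[2, 3] == pytest.approx(100.0)
        assert d[1, 2] == pytest.approx(100.0)
        assert d[1, 1] == pytest.approx(100.0 * math.sqrt(2), abs=1e-3)

    def test_matches_all_pairs_oracle_on_random_masks(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n = int(rng.integers(10, 21))
            mask = rng.random((n, n)) < 0.3
            if mask.all() or not mask.any():
                continue
            got = signed_distance_to_edge(_binary(mask)).values
            want = brute_force_signed_distance(mask, 100.0)
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-8)

    def test_sign_partitions_exactly_by_mask_and_never_zero(self):
        rng = np.random.default_rng(2)
        mask = rng.random((30, 30)) < 0.4
        mask[0, 0], mask[1, 1] = True, False
        d = signed_distance_to_edge(_binary(mask)).values
        assert (d[mask] < 0).all()
        assert (d[~mask] > 0).all()
        assert np.abs(d).min() >= 100.0

    def test_pixel_size_scaling_doubles_distances(self):
        rng = np.random.default_rng(3)
        mask = (rng.random((15, 15)) < 0.3).astype(np.int32)
        mask[7, 7], mask[0, 0] = 1, 0
        d1 = signed_distance_to_edge(_binary(mask, ps=100.0)).values
        d2 = signed_distance_to_edge(_binary(mask, ps=200.0)).values
        np.testing.assert_allclose(d2, 2 * d1)

    def test_nodata_propagates(self):
        mask = np.array([[1, 0, 0], [0, 0, 0], [0, 0, -9999]], dtype=np.int32)
        r = GridRaster(mask, 0, 300, 100.0, nodata=-9999)
        d = signed_distance_to_edge(r).values
        assert d[2, 2] == -9999

    @pytest.mark.parametrize("fill", [0, 1])
    def test_uniform_mask_rejected(self, fill):
        with pytest.raises(CovariateError):
            signed_distance_to_edge(_binary(np.full((4, 4), fill)))


class TestDistanceToFeatures:
    def test_feature_cells_are_zero_and_collinear_distance(self):
        mask = np.zeros((1, 5), dtype=int)
        mask[0, 0] = 1
        d = distance_to_features(_binary(mask)).values
        assert d[0, 0] == 0.0
        assert d[0, 3] == pytest.approx(300.0)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            mask = rng.random((20, 20)) < 0.1
            if not mask.any():
                mask[4, 4] = True
            got = distance_to_features(_binary(mask)).values
            rows, cols = np.indices(mask.shape)
            coords = np.column_stack([rows.ravel(), cols.ravel()]) * 100.0
            want = cdist(coords, coords[mask.ravel()]).min(axis=1).reshape(mask.shape)
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-8)

    def test_no_features_rejected(self):
        with pytest.raises(CovariateError):
            distance_to_features(_binary(np.zeros((3, 3))))


class TestSlope:
    def test_flat_dem_zero_slope(self):
        dem = GridRaster(np.full((5, 5), 123.0), 0, 500, 100.0)
        assert np.allclose(slope_from_elevation(dem).values, 0.0)

    def test_inclined_plane_closed_form(self):
        # rising 10 m per 100 m in x -> slope = atan(0.1) everywhere (interior)
        x = np.arange(6) * 100.0
        dem = GridRaster(np.tile(0.1 * x, (6, 1)), 0, 600, 100.0)
        slope = slope_from_elevation(dem).values
        expected = math.degrees(math.atan(0.1))
        np.testing.assert_allclose(slope[1:-1, 1:-1], expected, rtol=1e-10)
        assert expected == pytest.approx(5.7106, abs=1e-4)

    def test_rotation_symmetry_of_cone(self):
        n = 21
        r, c = np.indices((n, n)) - n // 2
        cone = GridRaster(-np.hypot(r, c) * 10.0, 0, n * 100.0, 100.0)
        slope = slope_from_elevation(cone).values
        np.testing.assert_allclose(slope, np.rot90(slope), atol=1e-9)

    def test_too_small_dem_rejected(self):
        with pytest.raises(CovariateError):
            slope_from_elevation(GridRaster(np.zeros((2, 2)), 0, 200, 100.0))


class TestCompositeLights:
    def test_single_raster_identity(self, grid_3x3):
        out = composite_lights([grid_3x3])
        np.testing.assert_array_equal(out.values, grid_3x3.values)

    def test_mean_of_two(self, grid_3x3):
        a = grid_3x3.like(np.full((3, 3), 10.0))
        b = grid_3x3.like(np.full((3, 3), 20.0))
        assert np.allclose(composite_lights([a, b]).values, 15.0)

    def test_nodata_in_any_input_yields_nodata(self, grid_3x3):
        va = np.full((3, 3), 10.0)
        va[0, 0] = -9999.0
        a = grid_3x3.like(va)
        b = grid_3x3.like(np.full((3, 3), 20.0))
        out = composite_lights([a, b]).values
        assert out[0, 0] == -9999.0
        assert out[1, 1] == 15.0

    def test_mean_bounded_by_inputs(self, grid_3x3):
        rng = np.random.default_rng(0)
        rasters = [grid_3x3.like(rng.uniform(0, 63, (3, 3))) for _ in range(3)]
        out = composite_lights(rasters).values
        lo = np.min([r.values for r in rasters], axis=0)
        hi = np.max([r.values for r in rasters], axis=0)
        assert ((out >= lo - 1e-12) & (out <= hi + 1e-12)).all()

    def test_misaligned_rejected(self, grid_3x3):
        other = GridRaster(np.zeros((3, 3)), 50, 300, 100.0)
        with pytest.raises(CovariateError):
            composite_lights([grid_3x3, other])


class TestBuildStack:
    @pytest.fixture
    def inputs(self):
        rng = np.random.default_rng(6)
        years = ("1990", "2000", "2010")
        template = GridRaster(np.zeros((12, 12)), 0, 1200, 100.0)
        dem = template.like(rng.uniform(0, 100, (12, 12)))
        rivers = np.zeros((12, 12), dtype=np.int32)
        rivers[5] = 1
        static = {
            "elevation": dem,
            "slope": slope_from_elevation(dem),
            "dist_water": distance_to_features(template.like(rivers)),
        }
        built, lights = {}, {}
        for t, y in enumerate(years):
            mask = np.zeros((12, 12), dtype=np.int32)
            mask[5 : 6 + t, 5 : 6 + t] = 1
            built[y] = template.like(mask)
            lights[y] = template.like(rng.uniform(0, 63, (12, 12)))
        return years, static, lights, built

    def test_first_year_has_single_built_distance_layer(self, inputs):
        years, static, lights, built = inputs
        stack = build_stack(0, years, static, lights, built)
        assert len(stack.layers) == 5
        assert stack.names == ["elevation", "slope", "dist_water", "lights",
                               "built_dist_1990"]

    def test_third_year_has_all_three_built_distances(self, inputs):
        years, static, lights, built = inputs
        stack = build_stack(2, years, static, lights, built)
        assert len(stack.layers) == 7
        assert stack.names[-3:] == ["built_dist_1990", "built_dist_2000",
                                    "built_dist_2010"]

    def test_deterministic(self, inputs):
        years, static, lights, built = inputs
        a = build_stack(1, years, static, lights, built)
        b = build_stack(1, years, static, lights, built)
        assert a.names == b.names
        for n in a.names:
            np.testing.assert_array_equal(a.layers[n].values, b.layers[n].values)

    def test_missing_built_year_rejected(self, inputs):
        years, static, lights, built = inputs
        del built["1990"]
        with pytest.raises(CovariateError):
            build_stack(2, years, static, lights, built)

    def test_misaligned_layers_rejected(self):
        a = GridRaster(np.zeros((3, 3)), 0, 300, 100.0)
        b = GridRaster(np.zeros((4, 4)), 0, 400, 100.0)
        with pytest.raises(CovariateError):
            CovariateStack(year="x", layers={"a": a, "b": b})
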