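import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bearconflict.raster import (GridRaster, GridSpec, RasterStack, crop_align,
                                 distance_to_feature, extract_values,
                                 log_transform, make_points, reclassify,
                                 resample_nearest)
from oracles import brute_force_distance


def grid_raster(values, cell=50.0, origin=(0.0, 0.0), **kw):
    return GridRaster(np.asarray(values), cell, origin, **kw)


class TestDistanceToFeature:
    def test_feature_cells_are_zero_and_pythagoras_elsewhere(self, bool_raster):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0] = True
        d = distance_to_feature(bool_raster(mask))
        assert d.values[0, 0] == 0.0
        # cell (3,4): 3 rows down, 4 cols right of the feature cell
        assert d.values[3, 4] == pytest.approx(50.0 * 5.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_grids(self, seed, bool_raster):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16)) < 0.1
        mask[rng.integers(16), rng.integers(16)] = True  # at least one feature
        d = distance_to_feature(bool_raster(mask, cell_size=50.0))
        np.testing.assert_allclose(d.values, brute_force_distance(mask, 50.0),
                                   rtol=1e-12)

    def test_never_exceeds_distance_to_any_sampled_feature(self, bool_raster):
        rng = np.random.default_rng(3)
        mask = rng.random((20, 20)) < 0.05
        mask[4, 7] = True
        d = distance_to_feature(bool_raster(mask, cell_size=10.0))
        rows, cols = np.nonzero(mask)
        for _ in range(50):
            i, j = rng.integers(20), rng.integers(20)
            k = rng.integers(len(rows))
            direct = 10.0 * np.hypot(rows[k] - i, cols[k] - j)
            assert d.values[i, j] <= direct + 1e-9

    def test_no_feature_cells_is_an_error(self, bool_raster):
        with pytest.raises(ValueError, match="no feature cells"):
            distance_to_feature(bool_raster(np.zeros((4, 4), dtype=bool)))


class TestReclassify:
    def test_identity_mapping_preserves_raster(self):
        r = grid_raster(np.arange(16).reshape(4, 4) % 16, kind="categorical")
        out = reclassify(r, {c: c for c in range(16)})
        np.testing.assert_array_equal(out.values, r.values)

    def test_sixteen_to_eight_class_scheme(self):
        # collapse 16 source codes into the 8-class cover scheme
        mapping = {c: c // 2 for c in range(16)}
        r = grid_raster(np.arange(16).reshape(4, 4), kind="categorical")
        out = reclassify(r, mapping)
        assert set(np.unique(out.values)) == set(range(8))

    def test_missing_code_errors_and_leaves_input_untouched(self):
        vals = np.array([[1, 2], [3, 4]])
        r = grid_raster(vals.copy(), kind="categorical")
        with pytest.raises(ValueError, match=r"missing codes.*\[4\]"):
            reclassify(r, {1: 0, 2: 0, 3: 1})
        np.testing.assert_array_equal(r.values, vals)

    def test_nodata_preserved(self):
        r = grid_raster(np.array([[1, -1], [2, 1]]), nodata=-1, kind="categorical")
        out = reclassify(r, {1: 10, 2: 20})
        assert out.values[0, 1] == -1
        np.testing.assert_array_equal(out.nodata_mask(), r.nodata_mask())


class TestLogTransform:
    def test_closed_forms(self):
        r = grid_raster(np.ones((3, 3)))
        assert np.all(log_transform(r, offset=0.0).values == 0.0)
        r2 = grid_raster(np.array([[0.0, np.e - 1.0]]))
        out = log_transform(r2, offset=1.0)
        np.testing.assert_allclose(out.values, [[0.0, 1.0]], atol=1e-15)

    def test_nonpositive_argument_rejected(self):
        with pytest.raises(ValueError, match="log undefined"):
            log_transform(grid_raster(np.array([[0.0, 1.0]])), offset=0.0)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0.0, 1e6), min_size=4, max_size=36))
    def test_preserves_cell_ordering(self, vals):
        n = int(np.sqrt(len(vals)))
        arr = np.asarray(vals[: n * n]).reshape(n, n)
        out = log_transform(grid_raster(arr), offset=1.0)
        order = np.argsort(arr.ravel(), kind="stable")
        assert np.all(np.diff(out.values.ravel()[order]) >= 0)

    def test_nodata_mask_unchanged(self):
        arr = np.array([[1.0, np.nan], [2.0, 3.0]])
        out = log_transform(grid_raster(arr), offset=1.0)
        np.testing.assert_array_equal(out.nodata_mask(), np.isnan(arr))


class TestResampleNearest:
    def test_identity_on_same_grid(self):
        rng = np.random.default_rng(0)
        r = grid_raster(rng.random((6, 8)))
        out = resample_nearest(r, r.grid)
        np.testing.assert_array_equal(out.values, r.values)

    def test_refining_a_constant_raster_stays_constant(self):
        r = grid_raster(np.full((4, 4), 3.5), cell=100.0)
        target = GridSpec(8, 8, 50.0, (0.0, 0.0))
        out = resample_nearest(r, target)
        assert np.all(out.values == 3.5)

    def test_coarsening_matches_nearest_centre_lookup(self):
        rng = np.random.default_rng(5)
        r = grid_raster(rng.random((12, 12)), cell=50.0)
        target = GridSpec(4, 4, 150.0, (0.0, 0.0))
        out = resample_nearest(r, target)
        for i in range(4):
            for j in range(4):
                # target centre
                xc = (j + 0.5) * 150.0
                yc = -(i + 0.5) * 150.0
                X, Y = r.grid.cell_centers()
                k = np.argmin((X - xc) ** 2 + (Y - yc) ** 2)
                assert out.values[i, j] == r.values.ravel()[k]

    def test_categorical_codes_never_interpolated(self):
        r = grid_raster(np.array([[0, 7], [7, 0]]), cell=100.0, kind="categorical")
        out = resample_nearest(r, GridSpec(4, 4, 50.0, (0.0, 0.0)))
        assert set(np.unique(out.values)) <= {0, 7}

    def test_disjoint_grids_error(self):
        r = grid_raster(np.ones((4, 4)))
        far = GridSpec(4, 4, 50.0, (1e6, -1e6))
        with pytest.raises(ValueError, match="disjoint"):
            resample_nearest(r, far)


class TestCropAlign:
    def test_crop_to_own_extent_is_identity(self):
        rng = np.random.default_rng(1)
        r = grid_raster(rng.random((5, 7)))
        out = crop_align({"a": r}, r.grid.extent)
        np.testing.assert_array_equal(out["a"].values, r.values)
        assert out["a"].grid == r.grid

    def test_offset_layers_share_one_grid(self):
        rng = np.random.default_rng(2)
        a = grid_raster(rng.random((10, 10)), origin=(0.0, 0.0))
        b = grid_raster(rng.random((10, 10)), origin=(100.0, -100.0))
        out = crop_align({"a": a, "b": b}, (100.0, 400.0, -400.0, -100.0))
        assert out["a"].grid == out["b"].grid
        assert out["a"].grid.origin == (100.0, -100.0)

    def test_values_preserved_where_grids_coincide(self):
        rng = np.random.default_rng(3)
        a = grid_raster(rng.random((10, 10)))
        out = crop_align({"a": a}, (100.0, 400.0, -400.0, -100.0))
        # target cell (i,j) corresponds to source cell (i+2, j+2)
        np.testing.assert_array_equal(out["a"].values, a.values[2:8, 2:8])


class TestExtractValues:
    def test_constant_raster_returns_constant(self):
        stack = RasterStack({"c": grid_raster(np.full((4, 4), 2.5))})
        pts = make_points([75.0], [-75.0], [1])
        out = extract_values(stack, pts)
        assert out.loc[0, "c"] == 2.5

    def test_shared_corner_resolves_to_lower_index_cell(self):
        vals = np.arange(16, dtype=float).reshape(4, 4)
        stack = RasterStack({"v": grid_raster(vals)})
        # (100, -100) is the shared corner of cells (1,1),(1,2),(2,1),(2,2);
        # half-open membership puts it in row 2, col 2
        out = extract_values(stack, make_points([100.0], [-100.0], [0]))
        assert out.loc[0, "v"] == vals[2, 2]

    def test_matches_index_arithmetic_on_random_points(self):
        rng = np.random.default_rng(7)
        vals = rng.random((9, 11))
        stack = RasterStack({"v": grid_raster(vals, cell=30.0)})
        x = rng.uniform(0, 11 * 30.0, 100)
        y = rng.uniform(-9 * 30.0, 0, 100)
        out = extract_values(stack, make_points(x, y, np.zeros(100, dtype=int)))
        expect = vals[np.floor(-y / 30.0).astype(int),
                      np.floor(x / 30.0).astype(int)]
        np.testing.assert_array_equal(out["v"].to_numpy(), expect)

    def test_outside_points_are_dropped_with_count(self, caplog):
        stack = RasterStack({"v": grid_raster(np.ones((4, 4)))})
        pts = make_points([50.0, 1e5], [-50.0, -1e5], [1, 1])
        with caplog.at_level("INFO"):
            out = extract_values(stack, pts)
        assert len(out) == 1
        assert "excluded 1" in caplog.text

    def test_extracting_at_cell_centres_reproduces_the_raster(self):
        rng = np.random.default_rng(8)
        vals = rng.random((6, 6))
        r = grid_raster(vals, cell=25.0)
        X, Y = r.grid.cell_centers()
        pts = make_points(X.ravel(), Y.ravel(), np.zeros(36, dtype=int))
        out = extract_values(RasterStack({"v": r}), pts)
        np.testing.assert_array_equal(
            out["v"].to_numpy().reshape(6, 6), vals)


def test_stack_rejects_misaligned_layers():
    a = grid_raster(np.ones((4, 4)))
    b = grid_raster(np.ones((4, 4)), origin=(10.0, 0.0))
    with pytest.raises(ValueError, match="not aligned"):
        RasterStack({"a": a, "b": b})
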