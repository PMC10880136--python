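"""Raster container, standardisation, extraction and grid indexing."""

import numpy as np
import pytest

from cumniche.env_grid import (
    EnvLayer,
    EnvStack,
    GridSpec,
    cell_id,
    extract_values,
    read_ascii_grid,
    read_stack,
    standardize_stack,
    write_ascii_grid,
    write_stack,
)


def _layer(values, name="v", origin=(0.0, 0.0), cell=1.0):
    return EnvLayer(name=name, values=np.ma.asarray(np.atleast_2d(values), dtype=float),
                    origin=origin, cell_size=cell)


class TestStandardize:
    def test_hand_computed_zscore_with_sample_sd(self):
        stack = EnvStack([_layer([[2.0, 4.0, 6.0]])])
        out, params = standardize_stack(stack)
        np.testing.assert_allclose(out.layers[0].values, [[-1.0, 0.0, 1.0]])
        assert params.means["v"] == 4.0
        assert params.sds["v"] == 2.0  # sample sd, n-1 denominator

    def test_already_standardised_layer_unchanged(self):
        vals = np.array([[-1.0, 0.0, 1.0]])
        vals = (vals - vals.mean()) / vals.std(ddof=1)
        out, _ = standardize_stack(EnvStack([_layer(vals)]))
        np.testing.assert_allclose(out.layers[0].values, vals, atol=1e-12)

    def test_constant_layer_errors_naming_the_layer(self):
        with pytest.raises(ValueError, match="constant layer 'v'"):
            standardize_stack(EnvStack([_layer([[7.0, 7.0, 7.0]])]))

    def test_fully_masked_layer_errors(self):
        vals = np.ma.MaskedArray([[1.0, 2.0]], mask=[[True, True]])
        with pytest.raises(ValueError, match="entirely masked"):
            standardize_stack(EnvStack([_layer(vals)]))

    def test_masked_cells_stay_masked_and_are_excluded_from_moments(self):
        vals = np.ma.MaskedArray([[2.0, 4.0, 6.0, 99.0]],
                                 mask=[[False, False, False, True]])
        out, params = standardize_stack(EnvStack([_layer(vals)]))
        assert params.means["v"] == 4.0
        assert out.layers[0].values.mask[0, 3]

    def test_output_mean_zero_sd_one(self, rng):
        vals = rng.normal(5, 3, size=(20, 20))
        out, _ = standardize_stack(EnvStack([_layer(vals)]))
        data = out.layers[0].values.compressed()
        assert abs(data.mean()) < 1e-9
        assert abs(data.std(ddof=1) - 1) < 1e-9

    def test_replaying_stored_params_is_bit_identical(self, rng):
        raw = EnvStack([_layer(rng.normal(size=(8, 8)))])
        out1, params = standardize_stack(raw)
        out2, _ = standardize_stack(raw, params=params)
        np.testing.assert_array_equal(
            out1.layers[0].values.data, out2.layers[0].values.data
        )


class TestExtract:
    def test_single_point_two_layers(self):
        stack = EnvStack([_layer([[0.5]], "a"), _layer([[-1.0]], "b")])
        m, kept = extract_values(stack, [(0.5, 0.5)])
        np.testing.assert_array_equal(m, [[0.5, -1.0]])
        np.testing.assert_array_equal(kept, [0])

    def test_point_on_masked_cell_dropped(self, toy_stack):
        m, kept = extract_values(toy_stack, [(1.5, 1.5)])  # the masked center
        assert m.shape == (0, 2)
        assert kept.size == 0

    def test_masked_point_dropped_order_preserved(self, toy_stack):
        # toy layer rows are north-first: value at (lon, lat) = 3*(2-floor(lat))+floor(lon)
        pts = [(0.5, 0.5), (1.5, 1.5), (2.5, 2.5)]
        m, kept = extract_values(toy_stack, pts)
        np.testing.assert_array_equal(kept, [0, 2])
        np.testing.assert_array_equal(m[:, 0], [6.0, 2.0])

    def test_out_of_extent_point_warns_and_drops(self, toy_stack):
        with pytest.warns(UserWarning, match="outside raster extent"):
            m, kept = extract_values(toy_stack, [(10.0, 10.0), (0.5, 0.5)])
        np.testing.assert_array_equal(kept, [1])

    def test_permutation_equivariance(self, toy_stack, rng):
        pts = np.column_stack([rng.uniform(0, 3, 30), rng.uniform(0, 3, 30)])
        m1, k1 = extract_values(toy_stack, pts)
        perm = rng.permutation(30)
        m2, k2 = extract_values(toy_stack, pts[perm])
        # rows correspond to the same original points in both calls
        orig2 = perm[k2]
        assert set(k1.tolist()) == set(orig2.tolist())
        lookup = {o: row for o, row in zip(orig2, m2)}
        for o, row in zip(k1, m1):
            np.testing.assert_array_equal(row, lookup[o])

    def test_top_right_edge_assigned_to_last_cell(self, toy_stack):
        m, kept = extract_values(toy_stack, [(3.0, 3.0)])
        assert kept.size == 1
        assert m[0, 0] == 2.0  # north-east corner cell


class TestCellId:
    @pytest.mark.parametrize(
        "lon, lat, expected",
        [
            (-180.0, -90.0, (0, 0)),
            (-179.875, -90.0, (0, 0)),
            (-179.75, -89.75, (1, 1)),
        ],
    )
    def test_floor_arithmetic(self, lon, lat, expected):
        assert cell_id(lon, lat, GridSpec(0.25)) == expected

    def test_every_point_maps_to_exactly_one_cell(self, rng):
        grid = GridSpec(0.25)
        pts = np.column_stack([rng.uniform(-180, 180, 200), rng.uniform(-90, 90, 200)])
        for lon, lat in pts:
            c1 = cell_id(lon, lat, grid)
            assert c1 == cell_id(lon, lat, grid)

    def test_nearby_points_span_at_most_two_cells_per_axis(self, rng):
        grid = GridSpec(0.25)
        for _ in range(50):
            lon, lat = rng.uniform(-179, 179), rng.uniform(-89, 89)
            dlon, dlat = rng.uniform(0, 0.249, 2)
            c1 = cell_id(lon, lat, grid)
            c2 = cell_id(lon + dlon, lat + dlat, grid)
            assert abs(c2[0] - c1[0]) <= 1 and abs(c2[1] - c1[1]) <= 1

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            cell_id(float("nan"), 0.0, GridSpec(1.0))


class TestStackValidation:
    def test_mismatched_geometry_rejected(self):
        with pytest.raises(ValueError, match="not co-registered"):
            EnvStack([_layer([[1.0, 2.0]], "a"), _layer([[1.0, 2.0]], "b", cell=2.0)])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            EnvStack([_layer([[1.0, 2.0]], "a"), _layer([[3.0, 4.0]], "a")])


class TestAsciiIO:
    def test_layer_roundtrip_preserves_values_mask_and_geometry(self, toy_layer, tmp_path):
        path = tmp_path / "t1.asc"
        write_ascii_grid(toy_layer, path)
        back = read_ascii_grid(path)
        np.testing.assert_array_equal(back.values.filled(-9999), toy_layer.values.filled(-9999))
        np.testing.assert_array_equal(
            np.ma.getmaskarray(back.values), np.ma.getmaskarray(toy_layer.values)
        )
        assert back.origin == toy_layer.origin
        assert back.cell_size == toy_layer.cell_size

    def test_stack_roundtrip_with_standardisation_sidecar(self, rng, tmp_path):
        stack = EnvStack([_layer(rng.normal(size=(5, 4)), "a"), _layer(rng.normal(size=(5, 4)), "b")])
        std, params = standardize_stack(stack)
        write_stack(std, tmp_path / "stack")
        back = read_stack(tmp_path / "stack")
        assert back.names == ["a", "b"]
        assert back.standardization.means == params.means
        np.testing.assert_allclose(back.layers[0].values, std.layers[0].values)
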