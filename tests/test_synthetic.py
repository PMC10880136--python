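"""Virtual landscapes, species and scenario bundles."""

import numpy as np
import pytest
from shapely.geometry import box

from cumniche.env_grid import extract_values
from cumniche.niche_breadth import breadth_from_points
from cumniche.synthetic import (
    PRESETS,
    VirtualSpecies,
    generate_regions,
    generate_stack,
    make_scenario,
    sample_occurrences,
    write_bundle,
)


class TestGenerateStack:
    def test_same_seed_bitwise_identical(self):
        s1 = generate_stack(16, 16, 3, seed=5)
        s2 = generate_stack(16, 16, 3, seed=5)
        for l1, l2 in zip(s1.layers, s2.layers):
            np.testing.assert_array_equal(l1.values.data, l2.values.data)

    def test_identity_mixing_keeps_layers_weakly_correlated(self):
        """Evenly spaced gradient directions plus independent noise: mean
        pairwise |r| stays below 0.2 across seeds."""
        rs = []
        for seed in range(20):
            stack = generate_stack(64, 64, 3, seed=seed)
            flat = np.column_stack([l.values.data.ravel() for l in stack.layers])
            c = np.corrcoef(flat, rowvar=False)
            rs.append(np.abs(c[np.triu_indices(3, 1)]))
        assert np.mean(rs) < 0.2

    def test_zero_smoothness_gives_pure_gradient(self):
        stack = generate_stack(32, 32, 1, smoothness=0.0, seed=0, rotation=0.0)
        vals = stack.layers[0].values.data
        xs = np.tile(np.arange(32, dtype=float), (32, 1))
        r = np.corrcoef(vals.ravel(), xs.ravel())[0, 1]
        assert r > 0.9999

    def test_standardised_output(self):
        stack = generate_stack(16, 16, 2, seed=1)
        for layer in stack.layers:
            data = layer.values.compressed()
            assert abs(data.mean()) < 1e-9
            assert abs(data.std(ddof=1) - 1) < 1e-9

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_stack(4, 4, 1)


class TestGenerateRegions:
    def test_nested_layout_boxes_inside_native(self):
        stack = generate_stack(64, 64, 2, smoothness=0.02, seed=3, rotation=0.0, folded=True)
        native, regions = generate_regions(stack, "nested", seed=3, m=8)
        from cumniche.synthetic import _env_box

        env_native = _env_box(stack, native)
        for geom in regions.regions.values():
            env_r = _env_box(stack, geom)
            for name in stack.names:
                assert env_r[name][0] >= env_native[name][0]
                assert env_r[name][1] <= env_native[name][1]

    def test_novel_layout_reaches_amplitude_target(self):
        stack = generate_stack(64, 64, 2, smoothness=0.02, seed=4, rotation=0.0)
        native, regions = generate_regions(stack, "novel", seed=4, m=6, novelty_target=2.0)
        from cumniche.synthetic import _env_box

        env_native = _env_box(stack, native)
        pooled_max = {n: -np.inf for n in stack.names}
        pooled_min = {n: np.inf for n in stack.names}
        for geom in regions.regions.values():
            env_r = _env_box(stack, geom)
            for n in stack.names:
                pooled_min[n] = min(pooled_min[n], env_r[n][0])
                pooled_max[n] = max(pooled_max[n], env_r[n][1])
        ratios = [
            (pooled_max[n] - pooled_min[n]) / (env_native[n][1] - env_native[n][0])
            for n in stack.names
        ]
        assert max(ratios) >= 2.0

    def test_zero_regions(self):
        stack = generate_stack(16, 16, 1, seed=0)
        _, regions = generate_regions(stack, "novel", seed=0, m=0)
        assert len(regions) == 0


class TestSampleOccurrences:
    def setup_method(self):
        self.stack = generate_stack(64, 64, 2, smoothness=0.02, seed=9, rotation=0.0)
        self.polygon = box(*self.stack.bounds)
        lo1, hi1 = -1.0, 1.0
        self.species = VirtualSpecies({"bio1": (lo1, hi1), "bio2": (-2.0, 2.0)})

    def test_amplitudes_approach_realised_box_widths(self):
        pts = sample_occurrences(self.species, self.stack, self.polygon, n=1500, seed=0)
        vals, _ = extract_values(self.stack, pts)
        amp1 = vals[:, 0].max() - vals[:, 0].min()
        assert 1.8 < amp1 <= 2.0 + 0.1  # near the bio1 box width of 2

    def test_completeness_truncates_the_box(self):
        pts = sample_occurrences(
            self.species, self.stack, self.polygon, n=500, completeness=0.5, seed=0
        )
        vals, _ = extract_values(self.stack, pts)
        # truncation is anchored at the low end of each axis
        assert vals[:, 0].max() <= 0.0 + 0.1
        assert vals[:, 0].min() >= -1.0 - 0.1

    def test_single_point_gives_zero_downstream_breadth(self):
        pts = sample_occurrences(self.species, self.stack, self.polygon, n=1, seed=0)
        vals, _ = extract_values(self.stack, pts)
        assert breadth_from_points(vals).breadth == 0.0

    def test_unsuitable_polygon_rejected(self):
        impossible = VirtualSpecies({"bio1": (50.0, 60.0)})
        with pytest.raises(ValueError, match="no suitable cells"):
            sample_occurrences(impossible, self.stack, self.polygon, n=5, seed=0)

    def test_ground_truth_breadth_recovery(self):
        """Complete sampling recovers the realised box breadth within 5%."""
        stack = generate_stack(160, 160, 2, smoothness=0.02, seed=11, rotation=0.0)
        polygon = box(*stack.bounds)
        species = VirtualSpecies({"bio1": (-1.2, 1.2), "bio2": (-1.2, 1.2)})
        errs = []
        for seed in range(5):
            pts = sample_occurrences(species, stack, polygon, n=2000, seed=seed)
            vals, _ = extract_values(stack, pts)
            realised = breadth_from_points(
                np.column_stack(
                    [l.values.data.ravel() for l in stack.layers]
                )[
                    species.suitability(
                        np.column_stack([l.values.data.ravel() for l in stack.layers]),
                        stack.names,
                    )
                ]
            ).breadth
            errs.append(abs(breadth_from_points(vals).breadth - realised) / realised)
        assert np.mean(errs) < 0.05


class TestScenarios:
    def test_same_seed_gives_identical_bundle(self):
        b1 = make_scenario("a", seed=3)
        b2 = make_scenario("a", seed=3)
        assert b1.occurrences.equals(b2.occurrences)
        for l1, l2 in zip(b1.stack.layers, b2.stack.layers):
            np.testing.assert_array_equal(l1.values.data, l2.values.data)
        assert b1.checklist == b2.checklist

    def test_collinear_blend_layer_present(self):
        b = make_scenario("a", seed=0)
        flat = np.column_stack([l.values.data.ravel() for l in b.stack.layers])
        c = np.corrcoef(flat, rowvar=False)
        assert abs(c[0, 2]) >= 0.7 or abs(c[1, 2]) >= 0.7

    def test_all_presets_build_consistent_bundles(self):
        for name, preset in PRESETS.items():
            b = make_scenario(name, seed=1)
            assert len(b.checklist) == preset.n_regions
            assert set(b.checklist) == set(b.regions.regions)
            assert len(b.occurrences) > preset.native_n // 2

    def test_written_bundle_is_ingestible(self, tmp_path):
        from cumniche.data_prep import (
            read_checklist_csv,
            read_occurrences_csv,
            read_rangemap_geojson,
            read_regions_geojson,
        )
        from cumniche.env_grid import read_stack

        b = make_scenario("a", seed=2)
        paths = write_bundle(b, tmp_path)
        stack = read_stack(paths["stack"])
        assert stack.names == b.stack.names
        occ = read_occurrences_csv(paths["occurrences"])
        assert len(occ) == len(b.occurrences)
        regions = read_regions_geojson(paths["regions"])
        assert set(regions.regions) == set(b.regions.regions)
        rm = read_rangemap_geojson(paths["ranges"])
        assert rm.features[0][1] == "Native"
        assert read_checklist_csv(paths["checklist"]) == sorted(b.checklist)
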