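"""Fold plans and the native / alien / background accumulation curves."""

import numpy as np
import pytest
from shapely.geometry import box

from cumniche.accumulation import (
    alien_curve,
    background_curve,
    make_fold_plan,
    native_curve,
    sample_background_points,
    RegionOrder,
)
from cumniche.data_prep import RegionSet
from cumniche.env_grid import EnvLayer, EnvStack
from cumniche.niche_breadth import breadth_from_points


def grid_stack(values_by_name, origin=(0.0, 0.0), cell=0.05):
    return EnvStack(
        [
            EnvLayer(n, np.ma.asarray(v).astype(float), origin, cell)
            for n, v in values_by_name.items()
        ]
    )


class TestFoldPlan:
    @pytest.mark.parametrize(
        "n, sizes, rule",
        [
            (2500, (100,) * 25, "per100"),
            (12, (1,) * 12, "per1"),
            (45, (10, 10, 10, 10, 5), "per10"),
            (30, (1,) * 30, "per1"),
            (31, (10, 10, 10, 1), "per10"),
            (1000, (10,) * 100, "per10"),
            (1001, (100,) * 10 + (1,), "per100"),
        ],
    )
    def test_regimes_and_remainders(self, n, sizes, rule):
        plan = make_fold_plan(n)
        assert plan.fold_sizes == sizes
        assert plan.rule_used == rule
        assert sum(plan.fold_sizes) == n

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(0)


class TestNativeCurve:
    def test_two_extreme_points_drive_the_jump(self):
        values = np.vstack([np.zeros((10, 2)), [[5.0, 0.0]], [[0.0, 5.0]]])
        curve = native_curve(values, n_reps=5, rng_seed=0)
        for row in curve.reps:
            jump = np.flatnonzero(row > 0)[0]
            assert np.all(row[:jump] == 0.0)
            assert row[-1] == 1.0

    def test_single_fold_gives_unit_curve(self):
        curve = native_curve([[0.0], [1.0]], n_reps=3, rng_seed=0)
        assert curve.n_steps == 2  # two records => two folds of one
        np.testing.assert_array_equal(curve.reps[:, -1], 1.0)

    def test_rows_non_decreasing_and_end_exactly_at_one(self, rng):
        values = rng.normal(size=(57, 3))
        curve = native_curve(values, n_reps=10, rng_seed=1)
        assert np.all(np.diff(curve.reps, axis=1) >= 0)
        assert np.all(curve.reps[:, -1] == 1.0)

    def test_zero_reference_breadth_propagates(self):
        with pytest.raises(ValueError, match="reference niche breadth is zero"):
            native_curve(np.zeros((5, 2)), rng_seed=0)

    def test_seed_determinism_bitwise(self, rng):
        values = rng.normal(size=(40, 2))
        c1 = native_curve(values, rng_seed=7)
        c2 = native_curve(values, rng_seed=7)
        np.testing.assert_array_equal(c1.reps, c2.reps)
        c3 = native_curve(values, rng_seed=8)
        assert not np.array_equal(c1.reps, c3.reps)
        np.testing.assert_array_equal(c3.reps[:, -1], 1.0)


class TestAlienCurve:
    native = np.array([[0.0, 0.0], [1.0, 1.0]])

    def test_nested_regions_give_constant_one(self):
        regions = {"A": [[0.5, 0.5]], "B": [[0.2, 0.8], [0.9, 0.1]]}
        curve, _ = alien_curve(self.native, regions, n_reps=4, rng_seed=0)
        np.testing.assert_array_equal(curve.reps, 1.0)

    def test_amplitude_doubling_region_fixes_final_value(self):
        regions = {
            "doubler": [[2.0, 0.5]],  # doubles variable 0's amplitude
            "nested1": [[0.5, 0.5]],
            "nested2": [[0.1, 0.9]],
        }
        curve, _ = alien_curve(self.native, regions, n_reps=10, rng_seed=3)
        np.testing.assert_allclose(curve.reps[:, -1], 2.0)

    def test_single_region_ratio(self):
        curve, order = alien_curve(self.native, {"only": [[2.0, 1.0]]}, rng_seed=0)
        assert curve.n_steps == 1
        np.testing.assert_allclose(curve.reps, 2.0)
        assert order.region_ids == ["only"]

    def test_rows_non_decreasing_and_at_least_one(self, rng):
        regions = {f"R{i}": rng.normal(size=(4, 2)) for i in range(6)}
        curve, _ = alien_curve(rng.normal(size=(20, 2)), regions, rng_seed=5)
        assert np.all(curve.reps >= 1.0)
        assert np.all(np.diff(curve.reps, axis=1) >= 0)

    def test_empty_region_kept_as_step_and_flagged(self):
        regions = {"full": [[2.0, 0.5]], "empty": np.empty((0, 2))}
        curve, _ = alien_curve(self.native, regions, rng_seed=0)
        assert curve.n_steps == 2
        assert any("empty" in f for f in curve.flags)

    def test_no_alien_records_rejected(self):
        with pytest.raises(ValueError):
            alien_curve(self.native, {}, rng_seed=0)

    def test_final_step_matches_batch_oracle(self, rng):
        """Per repetition, the last curve value equals a from-scratch breadth
        on the pooled native + alien matrix."""
        native = rng.normal(size=(15, 3))
        regions = {f"R{i}": rng.normal(size=(5, 3)) for i in range(4)}
        curve, _ = alien_curve(native, regions, rng_seed=2)
        pooled = np.vstack([native] + list(regions.values()))
        expected = (
            breadth_from_points(pooled).breadth / breadth_from_points(native).breadth
        )
        np.testing.assert_array_equal(curve.reps[:, -1], expected)


class TestBackgroundCurve:
    def make_inputs(self, rng):
        grad = np.tile(np.linspace(-2, 2, 40), (40, 1))
        stack = grid_stack({"v1": grad, "v2": grad.T})
        native = np.array([[-1.0, -1.0], [0.0, 0.0]])
        regions = RegionSet({"A": box(0.2, 0.2, 1.0, 1.0), "B": box(1.2, 0.2, 1.9, 1.0)})
        order = RegionOrder([["A", "B"], ["B", "A"]])
        return stack, native, regions, order

    def test_rows_non_decreasing_and_at_least_one(self, rng):
        stack, native, regions, order = self.make_inputs(rng)
        curve = background_curve(native, regions, stack, order, cell_size=0.25, rng_seed=0)
        assert np.all(curve.reps >= 1.0)
        assert np.all(np.diff(curve.reps, axis=1) >= 0)

    def test_all_nodata_region_flagged_and_contributes_nothing(self, rng):
        grad = np.ma.MaskedArray(np.tile(np.linspace(-2, 2, 40), (40, 1)))
        grad[:, 24:] = np.ma.masked  # mask everything east of x = 1.2
        stack = grid_stack({"v1": grad})
        regions = RegionSet({"A": box(0.2, 0.2, 1.0, 1.0), "B": box(1.3, 0.2, 1.9, 1.0)})
        order = RegionOrder([["A", "B"]])
        native = np.array([[-3.0], [3.0]])
        curve = background_curve(native, regions, stack, order, cell_size=0.25, rng_seed=0)
        assert any("B" in f for f in curve.flags)
        assert curve.reps[0, 0] == curve.reps[0, 1]

    def test_background_dominates_alien_when_occurrences_included(self, rng):
        stack, native, regions, order = self.make_inputs(rng)
        alien_vals = {"A": rng.uniform(-0.5, 1.5, size=(6, 2)), "B": rng.uniform(-0.5, 1.5, size=(6, 2))}
        from cumniche.accumulation import alien_curve as ac

        acurve, order2 = ac(native, alien_vals, n_reps=3, rng_seed=1)
        bcurve = background_curve(
            native, regions, stack, order2, cell_size=0.25, rng_seed=1,
            include_alien_occurrences=True, alien_values_by_region=alien_vals,
        )
        assert np.all(bcurve.reps >= acurve.reps - 1e-12)

    def test_seed_determinism(self, rng):
        stack, native, regions, order = self.make_inputs(rng)
        c1 = background_curve(native, regions, stack, order, rng_seed=9)
        c2 = background_curve(native, regions, stack, order, rng_seed=9)
        np.testing.assert_array_equal(c1.reps, c2.reps)

    def test_one_point_per_cell(self, rng):
        stack, _, regions, _ = self.make_inputs(rng)
        pts = sample_background_points(regions.regions["A"], stack, cell_size=0.25, rng=0)
        # region A spans 0.2-1.0 on both axes: cells with centers inside are
        # the 3x3 block at 0.25-1.0
        assert pts.shape == (9, 2)
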