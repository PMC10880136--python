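"""Construction of the three niche accumulation curves.

*Native curve*: native occurrences are shuffled into folds (fold size set by
the sample-size regime), folds are added one at a time, and at each step the
partial niche breadth is divided by the full native breadth — a trajectory
from near zero to exactly one. *Alien curve*: invaded regions are added in
random order; at each step the breadth of native ∪ accumulated alien records
is divided by the native breadth, giving values ≥ 1. *Background curve*: the
same region orders, but each region is represented by one random point per
coarse background grid cell (0.25° by default), showing the maximum
expansion the regions' conditions would allow.

Every curve is repeated (10 repetitions by default, reshuffling fold
membership / region order each time) and summarised by the pointwise mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .data_prep import RegionSet
from .env_grid import EnvStack, extract_values
from .niche_breadth import breadth_from_points, breadth_ratio, update

__all__ = [
    "BACKGROUND_CELL_DEG",
    "FoldPlan",
    "Curve",
    "RegionOrder",
    "make_fold_plan",
    "native_curve",
    "alien_curve",
    "sample_background_points",
    "background_curve",
    "curves_to_dataframe",
    "plot_curves",
]

#: Default background-sampling grid resolution in degrees (~25 km at the equator).
BACKGROUND_CELL_DEG = 0.25

NATIVE_KIND = "native"
ALIEN_KIND = "alien"
BACKGROUND_KIND = "background"


@dataclass(frozen=True)
class FoldPlan:
    """Fold sizes for the native curve under the sample-size regime rules."""

    fold_sizes: tuple[int, ...]
    rule_used: str

    @property
    def n_folds(self) -> int:
        return len(self.fold_sizes)


def make_fold_plan(n: int) -> FoldPlan:
    """Partition n native occurrences into folds.

    More than 1000 records: folds of 100; 31–1000: folds of 10; 30 or fewer:
    folds of 1. A final smaller fold keeps the remainder, so every record
    participates and the reference breadth uses the full data.
    """
    if n < 1:
        raise ValueError("need at least one occurrence")
    if n > 1000:
        size, rule = 100, "per100"
    elif n > 30:
        size, rule = 10, "per10"
    else:
        size, rule = 1, "per1"
    sizes = [size] * (n // size)
    if n % size:
        sizes.append(n % size)
    return FoldPlan(tuple(sizes), rule)


@dataclass
class RegionOrder:
    """Per-repetition permutations of the alien region ids.

    Shared between the alien and background curves of one run so the two are
    directly comparable step by step.
    """

    orders: list[list[str]]

    def __post_init__(self) -> None:
        ref = sorted(self.orders[0])
        for row in self.orders:
            if sorted(row) != ref:
                raise ValueError("every row must be a permutation of the same regions")

    @property
    def region_ids(self) -> list[str]:
        return sorted(self.orders[0])

    @property
    def n_reps(self) -> int:
        return len(self.orders)


@dataclass
class Curve:
    """Accumulation trajectories (one row per repetition) and their mean."""

    kind: str
    reps: np.ndarray  # repetition × step matrix of breadth ratios
    origin: float  # conceptual value at step 0 (0 for native, 1 otherwise)
    reference_breadth: float
    total_breadth: float  # pooled-data breadth at the final step
    step_labels: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reps = np.atleast_2d(np.asarray(self.reps, dtype=float))

    @property
    def n_reps(self) -> int:
        return self.reps.shape[0]

    @property
    def n_steps(self) -> int:
        return self.reps.shape[1]

    @property
    def x(self) -> np.ndarray:
        return np.arange(1, self.n_steps + 1)

    @property
    def mean(self) -> np.ndarray:
        return self.reps.mean(axis=0)

    @property
    def final_mean(self) -> float:
        return float(self.mean[-1])


def _accumulate_ratios(
    reference, chunks: list[np.ndarray]
) -> np.ndarray:
    """Cumulative breadth ratio as chunks of points are folded in."""
    state = None
    out = np.empty(len(chunks))
    for i, chunk in enumerate(chunks):
        if state is None:
            state = breadth_from_points(chunk, reference.variables)
        else:
            state = update(state, chunk)
        out[i] = breadth_ratio(state, reference)
    return out


def native_curve(
    native_values: np.ndarray,
    n_reps: int = 10,
    rng_seed: int | np.random.Generator = 0,
    variables: list[str] | None = None,
) -> Curve:
    """Native niche accumulation curve.

    Each repetition reshuffles the records into fresh folds; at step k the
    breadth of the first k folds is divided by the full native breadth, so
    every repetition is non-decreasing and ends at exactly 1.
    """
    values = np.asarray(native_values, dtype=float)
    reference = breadth_from_points(values, variables)
    if reference.breadth <= 0:
        breadth_ratio(reference, reference)  # raises the informative error
    plan = make_fold_plan(values.shape[0])
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    edges = np.cumsum((0,) + plan.fold_sizes)
    reps = np.empty((n_reps, plan.n_folds))
    for r in range(n_reps):
        perm = rng.permutation(values.shape[0])
        chunks = [values[perm[edges[i] : edges[i + 1]]] for i in range(plan.n_folds)]
        # final fold pools all records; extrema are exact, so the last
        # ratio is exactly 1 with no floating fuzz
        reps[r] = _accumulate_ratios(reference, chunks)
    return Curve(
        kind=NATIVE_KIND,
        reps=reps,
        origin=0.0,
        reference_breadth=reference.breadth,
        total_breadth=reference.breadth,
        step_labels=[f"fold_{i + 1}" for i in range(plan.n_folds)],
    )


def alien_curve(
    native_values: np.ndarray,
    alien_values_by_region: dict[str, np.ndarray],
    n_reps: int = 10,
    rng_seed: int | np.random.Generator = 0,
    variables: list[str] | None = None,
) -> tuple[Curve, RegionOrder]:
    """Alien niche accumulation curve over randomly ordered regions.

    At step k the breadth of native ∪ the first k regions' records is
    divided by the native breadth; values are ≥ 1 and non-decreasing.
    Regions without surviving records remain as steps (adding nothing) and
    are flagged. The region orders are returned for reuse by the background
    curve.
    """
    if not alien_values_by_region:
        raise ValueError("no alien records in any region")
    values = np.asarray(native_values, dtype=float)
    reference = breadth_from_points(values, variables)
    if reference.breadth <= 0:
        breadth_ratio(reference, reference)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    region_ids = sorted(alien_values_by_region)
    k = len(reference.variables)
    empty_regions = [
        rid for rid in region_ids if np.asarray(alien_values_by_region[rid]).size == 0
    ]
    orders = [list(np.array(region_ids)[rng.permutation(len(region_ids))]) for _ in range(n_reps)]
    reps = np.empty((n_reps, len(region_ids)))
    pooled_final = reference
    for r, order in enumerate(orders):
        state = reference
        for step, rid in enumerate(order):
            vals = np.asarray(alien_values_by_region[rid], dtype=float).reshape(-1, k)
            state = update(state, vals)
            reps[r, step] = breadth_ratio(state, reference)
        pooled_final = state
    flags = [f"region {rid} has no surviving records" for rid in empty_regions]
    curve = Curve(
        kind=ALIEN_KIND,
        reps=reps,
        origin=1.0,
        reference_breadth=reference.breadth,
        total_breadth=pooled_final.breadth,
        step_labels=[f"region_{i + 1}" for i in range(len(region_ids))],
        flags=flags,
    )
    return curve, RegionOrder(orders)


def sample_background_points(
    region: BaseGeometry,
    stack: EnvStack,
    cell_size: float = BACKGROUND_CELL_DEG,
    rng: np.random.Generator | int = 0,
    cell_rule: str = "center",
    max_redraws: int = 10,
) -> np.ndarray:
    """One uniformly random point per background grid cell in a region.

    Cells belong to a region when their center lies inside it (default), or
    when they overlap it at all (``cell_rule='overlap'``). Points landing on
    nodata are redrawn up to ``max_redraws`` times, then the cell is skipped.
    Returns the extracted environmental values (one row per surviving cell).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    minx, miny, maxx, maxy = region.bounds
    x0, y0 = stack.origin
    c0 = int(np.floor((minx - x0) / cell_size))
    c1 = int(np.floor((maxx - x0) / cell_size))
    r0 = int(np.floor((miny - y0) / cell_size))
    r1 = int(np.floor((maxy - y0) / cell_size))
    rows = []
    for ci in range(c0, c1 + 1):
        for ri in range(r0, r1 + 1):
            cx0 = x0 + ci * cell_size
            cy0 = y0 + ri * cell_size
            if cell_rule == "center":
                if not shapely.intersects_xy(
                    region, cx0 + cell_size / 2, cy0 + cell_size / 2
                ):
                    continue
            elif cell_rule == "overlap":
                if not region.intersects(
                    shapely.box(cx0, cy0, cx0 + cell_size, cy0 + cell_size)
                ):
                    continue
            else:
                raise ValueError(f"unknown cell_rule {cell_rule!r}")
            for _ in range(max_redraws + 1):
                lon = cx0 + rng.uniform(0, cell_size)
                lat = cy0 + rng.uniform(0, cell_size)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    vals, kept = extract_values(stack, [(lon, lat)])
                if kept.size:
                    rows.append(vals[0])
                    break
    return np.asarray(rows, dtype=float).reshape(len(rows), len(stack.layers))


def background_curve(
    native_values: np.ndarray,
    regions: RegionSet,
    stack: EnvStack,
    order: RegionOrder,
    cell_size: float = BACKGROUND_CELL_DEG,
    rng_seed: int | np.random.Generator = 0,
    include_alien_occurrences: bool = False,
    alien_values_by_region: dict[str, np.ndarray] | None = None,
    cell_rule: str = "center",
    variables: list[str] | None = None,
) -> Curve:
    """Background accumulation curve over the same region orders.

    Each region contributes one random point per background grid cell
    (sampled once per run and reused across repetitions; only the region
    order varies). Step k divides the breadth of native ∪ background points
    of the first k regions (∪ those regions' alien records if requested) by
    the native breadth.
    """
    values = np.asarray(native_values, dtype=float)
    reference = breadth_from_points(values, variables)
    if reference.breadth <= 0:
        breadth_ratio(reference, reference)
    if include_alien_occurrences and alien_values_by_region is None:
        raise ValueError(
            "include_alien_occurrences requires alien_values_by_region"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    k = len(reference.variables)
    region_ids = order.region_ids
    missing = set(region_ids) - set(regions.regions)
    if missing:
        raise ValueError(f"order references unknown regions: {sorted(missing)}")
    bg: dict[str, np.ndarray] = {}
    flags = []
    for rid in region_ids:  # sorted: sampling order independent of RegionOrder
        pts = sample_background_points(
            regions.regions[rid], stack, cell_size=cell_size, rng=rng,
            cell_rule=cell_rule,
        )
        if pts.shape[0] == 0:
            flags.append(f"region {rid} has no valid background cells")
        if include_alien_occurrences:
            extra = np.asarray(alien_values_by_region.get(rid, np.empty((0, k))),
                               dtype=float).reshape(-1, k)
            pts = np.vstack([pts, extra]) if pts.size else extra
        bg[rid] = pts
    reps = np.empty((order.n_reps, len(region_ids)))
    pooled_final = reference
    for r, row in enumerate(order.orders):
        state = reference
        for step, rid in enumerate(row):
            state = update(state, bg[rid])
            reps[r, step] = breadth_ratio(state, reference)
        pooled_final = state
    return Curve(
        kind=BACKGROUND_KIND,
        reps=reps,
        origin=1.0,
        reference_breadth=reference.breadth,
        total_breadth=pooled_final.breadth,
        step_labels=[f"region_{i + 1}" for i in range(len(region_ids))],
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Serialisation and plotting


def curves_to_dataframe(curves: dict[str, Curve]) -> pd.DataFrame:
    """Long-form table: curve_kind, repetition, step, ratio."""
    frames = []
    for kind, curve in curves.items():
        for r in range(curve.n_reps):
            frames.append(
                pd.DataFrame(
                    {
                        "curve_kind": kind,
                        "repetition": r + 1,
                        "step": curve.x,
                        "ratio": curve.reps[r],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def plot_curves(
    curves: dict[str, Curve], path: str | Path | None = None, species: str = ""
):
    """Two-panel plot: native curve (green) and alien (red) vs background
    (blue), each with per-repetition grey traces."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    native = curves.get(NATIVE_KIND)
    if native is not None:
        for r in range(native.n_reps):
            axes[0].plot(native.x, native.reps[r], color="0.7", lw=0.8)
        axes[0].plot(native.x, native.mean, color="forestgreen", lw=2)
        axes[0].set_ylim(0, 1.05)
    axes[0].set_xlabel("native folds included")
    axes[0].set_ylabel("proportion of native niche breadth")
    colors = {ALIEN_KIND: ("red", "-"), BACKGROUND_KIND: ("royalblue", "-")}
    for kind, (color, ls) in colors.items():
        curve = curves.get(kind)
        if curve is None:
            continue
        for r in range(curve.n_reps):
            axes[1].plot(curve.x, curve.reps[r], color="0.7", lw=0.8,
                         ls="--" if kind == ALIEN_KIND else "-")
        axes[1].plot(curve.x, curve.mean, color=color, ls=ls, lw=2, label=kind)
    axes[1].set_xlabel("alien regions included")
    axes[1].set_ylabel("niche breadth ratio (native = 1)")
    axes[1].legend()
    if species:
        fig.suptitle(species)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
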