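"""Virtual species and landscapes with known ground truth.

Every generator is seeded and bitwise reproducible, and writes the same
formats the real pipeline reads, so the fixtures double as end-to-end tests.

The landscape is a stack of environmental layers, each a linear spatial
gradient in a fixed direction plus smoothed Gaussian noise, standardised to
zero mean and unit sd. With low noise the mapping between geography and
environment is tight, which makes the designed outcomes analytic: a virtual
species occupies an axis-aligned box in standardised environmental space, so
its true niche breadth is the product of the box widths, and accumulation
curves follow the order statistics of uniform range accumulation.

Scenario presets reproduce the four outcome regimes:

* ``a`` — native range sampled uniformly (native curve saturates) and many
  records per invaded region (alien curve saturates in the first steps),
  with the regions' conditions extending past the species' tolerance box
  (background headroom).
* ``b`` — as ``a`` but native sampling is clustered along the dominant
  gradient, so rare outlying records keep stretching the native envelope and
  the native curve never flattens.
* ``c`` — as ``a`` but only one record per invaded region: the species' box
  spans the regions, yet each region contributes a single draw, so the alien
  envelope keeps growing with every region added.
* ``d`` — clustered native sampling and sparse alien records.
* ``nested`` — a mirrored (folded) gradient landscape where the invaded
  regions offer only conditions already inside the native envelope: the
  alien curve sits at exactly 1 and the background curve is flat, the
  diagnostic signature of environmental nestedness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import box as shapely_box
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry.base import BaseGeometry

from .data_prep import RegionSet
from .env_grid import EnvLayer, EnvStack, standardize_stack, write_stack

__all__ = [
    "VirtualSpecies",
    "ScenarioPreset",
    "ScenarioBundle",
    "PRESETS",
    "generate_stack",
    "generate_regions",
    "sample_occurrences",
    "make_scenario",
    "write_bundle",
]


@dataclass(frozen=True)
class VirtualSpecies:
    """A species with an axis-aligned tolerance box in standardised space.

    ``niche_box`` maps a layer name to its (low, high) tolerance limits.
    Suitability is binary (inside the box) by default; ``logistic_width`` > 0
    softens the box edges for robustness experiments.
    """

    niche_box: dict[str, tuple[float, float]]
    logistic_width: float = 0.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.niche_box.items():
            if not lo < hi:
                raise ValueError(f"niche box for {name!r}: low must be < high")

    @property
    def true_breadth(self) -> float:
        return float(np.prod([hi - lo for lo, hi in self.niche_box.values()]))

    def suitability(
        self, values: np.ndarray, names: list[str], rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Boolean suitability per row of a point × layer matrix."""
        values = np.asarray(values, dtype=float)
        ok = np.ones(values.shape[0], dtype=bool)
        if self.logistic_width <= 0:
            for j, n in enumerate(names):
                if n in self.niche_box:
                    lo, hi = self.niche_box[n]
                    ok &= (values[:, j] >= lo) & (values[:, j] <= hi)
            return ok
        rng = rng or np.random.default_rng()
        p = np.ones(values.shape[0])
        w = self.logistic_width
        for j, n in enumerate(names):
            if n in self.niche_box:
                lo, hi = self.niche_box[n]
                p *= 1.0 / (1.0 + np.exp(-(values[:, j] - lo) / w))
                p *= 1.0 / (1.0 + np.exp((values[:, j] - hi) / w))
        return rng.uniform(size=p.size) < p


def generate_stack(
    n_cols: int = 64,
    n_rows: int = 64,
    k_vars: int = 2,
    smoothness: float = 1.5,
    seed: int | np.random.Generator = 0,
    cell_size: float = 0.05,
    origin: tuple[float, float] = (0.0, 0.0),
    names: list[str] | None = None,
    mixing: np.ndarray | None = None,
    rotation: float | None = None,
    folded: bool = False,
) -> EnvStack:
    """Generate a standardised stack of gradient + noise layers.

    Each base layer is a linear gradient in direction ``rotation + i*pi/k``
    (rotation drawn at random when not given) plus ``smoothness`` times a
    unit-sd smoothed-noise field; evenly spaced directions keep the base
    layers close to uncorrelated. ``mixing`` (an out × base matrix) blends
    base layers into the output layers, deliberately inducing collinearity
    for tests of the variable-selection step. ``folded`` mirrors the
    x-coordinate (a tent map), making geographically distant places share
    environments — the ingredient for nestedness fixtures.
    """
    if n_cols < 8 or n_rows < 8 or k_vars < 1:
        raise ValueError("need at least an 8×8 grid and one variable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rot = rng.uniform(0, np.pi) if rotation is None else float(rotation)
    xs = (np.arange(n_cols) + 0.5) / n_cols
    ys = (np.arange(n_rows) + 0.5) / n_rows
    X, Y = np.meshgrid(xs, ys[::-1])  # row 0 is the northern edge
    if folded:
        X = 1.0 - np.abs(2.0 * X - 1.0)
    base = []
    sigma = max(1.0, min(n_rows, n_cols) / 16)
    for i in range(k_vars):
        theta = rot + i * np.pi / k_vars
        grad = np.cos(theta) * X + np.sin(theta) * Y
        grad = (grad - grad.mean()) / grad.std()
        noise = gaussian_filter(rng.standard_normal((n_rows, n_cols)), sigma)
        noise = (noise - noise.mean()) / noise.std()
        base.append(grad + smoothness * noise)
    base = np.asarray(base)
    if mixing is not None:
        mixing = np.asarray(mixing, dtype=float)
        if mixing.shape[1] != k_vars:
            raise ValueError("mixing matrix columns must match k_vars")
        out = np.einsum("ok,kij->oij", mixing, base)
    else:
        out = base
    if names is None:
        names = [f"bio{i + 1}" for i in range(out.shape[0])]
    layers = [
        EnvLayer(name=n, values=np.ma.asarray(v), origin=origin, cell_size=cell_size)
        for n, v in zip(names, out)
    ]
    stack, _ = standardize_stack(EnvStack(layers))
    return stack


def _frac_box(stack: EnvStack, fx: tuple[float, float], fy: tuple[float, float]) -> BaseGeometry:
    """Axis-aligned rectangle given as fractions of the stack extent."""
    xmin, ymin, xmax, ymax = stack.bounds
    w, h = xmax - xmin, ymax - ymin
    return shapely_box(xmin + fx[0] * w, ymin + fy[0] * h, xmin + fx[1] * w, ymin + fy[1] * h)


def _env_box(stack: EnvStack, polygon: BaseGeometry) -> dict[str, tuple[float, float]]:
    """Per-layer (min, max) of cell values whose centers fall in a polygon."""
    nrows, ncols = stack.shape
    ref = stack.layers[0]
    lons = np.array([ref.cell_center(0, c)[0] for c in range(ncols)])
    lats = np.array([ref.cell_center(r, 0)[1] for r in range(nrows)])
    LON, LAT = np.meshgrid(lons, lats)
    inside = shapely.contains_xy(polygon, LON.ravel(), LAT.ravel()).reshape(nrows, ncols)
    inside &= stack.valid_mask()
    if not inside.any():
        raise ValueError("polygon contains no valid cells")
    return {
        layer.name: (
            float(np.min(layer.values.data[inside])),
            float(np.max(layer.values.data[inside])),
        )
        for layer in stack.layers
    }


def generate_regions(
    stack: EnvStack,
    layout: str = "novel",
    seed: int | np.random.Generator = 0,
    m: int = 10,
    novelty_target: float = 1.5,
    max_attempts: int = 50,
) -> tuple[BaseGeometry, RegionSet]:
    """Native polygon plus m alien rectangles with controlled novelty.

    ``layout='novel'``: alien regions tile a block adjacent to the native
    rectangle along the dominant gradient, every region spanning the block's
    full gradient extent — so a single region already offers all the novel
    conditions. ``layout='two-sided'``: two blocks, east and north of the
    native rectangle, sliced *along* their respective gradients so each
    region contributes its own environmental increment and the pooled
    novelty accrues region by region. ``layout='nested'``: alien regions sit
    on the mirrored arm of a folded landscape so every region's
    environmental box is inside the native box (requires a stack built with
    ``folded=True``). For novel/two-sided the pooled alien amplitude must
    reach ``novelty_target`` times the native amplitude on at least one
    variable. The achieved configuration is verified on the stack's actual
    values and re-jittered up to ``max_attempts`` times before erroring.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if m == 0:
        native = _frac_box(stack, (0.05, 0.3), (0.1, 0.9))
        return native, RegionSet({})
    last_diag = ""
    for _ in range(max_attempts):
        jx = rng.uniform(-0.01, 0.01)
        if layout in {"novel", "two-sided"}:
            if layout == "novel":
                native = _frac_box(stack, (0.05, 0.3), (0.1, 0.9))
                block_x = (0.3, min(0.95 + jx, 0.98))
                band = (0.9 - 0.1) / m
                regions = {
                    f"R{i + 1:02d}": _frac_box(
                        stack, block_x, (0.1 + i * band, 0.1 + (i + 1) * band)
                    )
                    for i in range(m)
                }
            else:
                if m % 2:
                    raise ValueError("two-sided layout needs an even region count")
                half = m // 2
                native = _frac_box(stack, (0.05, 0.3), (0.05, 0.55))
                ex = (0.95 - 0.3) / half  # east block sliced along x
                ny = (0.95 - 0.55) / half  # north block sliced along y
                regions = {}
                for i in range(half):
                    regions[f"R{i + 1:02d}"] = _frac_box(
                        stack, (0.3 + i * ex, 0.3 + (i + 1) * ex), (0.05, 0.55)
                    )
                for i in range(half):
                    regions[f"R{half + i + 1:02d}"] = _frac_box(
                        stack, (0.05, 0.3), (0.55 + i * ny, 0.55 + (i + 1) * ny)
                    )
            env_native = _env_box(stack, native)
            pooled = {
                n: (
                    min(_env_box(stack, g)[n][0] for g in regions.values()),
                    max(_env_box(stack, g)[n][1] for g in regions.values()),
                )
                for n in stack.names
            }
            ratios = {
                n: (pooled[n][1] - pooled[n][0])
                / max(env_native[n][1] - env_native[n][0], 1e-12)
                for n in stack.names
            }
            if max(ratios.values()) >= novelty_target:
                return native, RegionSet(regions)
            last_diag = f"novelty ratios {ratios} < target {novelty_target}"
        elif layout == "nested":
            native = _frac_box(stack, (0.05, 0.4), (0.1, 0.9))
            band = (0.75 - 0.25) / m
            regions = {
                f"R{i + 1:02d}": _frac_box(
                    stack,
                    (0.70 + jx, 0.85 + jx),
                    (0.25 + i * band, 0.25 + (i + 1) * band),
                )
                for i in range(m)
            }
            env_native = _env_box(stack, native)
            ok = True
            for rid, g in regions.items():
                env_r = _env_box(stack, g)
                for n in stack.names:
                    if not (
                        env_r[n][0] >= env_native[n][0] and env_r[n][1] <= env_native[n][1]
                    ):
                        ok = False
                        last_diag = (
                            f"region {rid} variable {n}: {env_r[n]} not inside "
                            f"native {env_native[n]}"
                        )
            if ok:
                return native, RegionSet(regions)
        else:
            raise ValueError(f"unknown layout {layout!r}")
    raise ValueError(f"could not attain {layout!r} layout target: {last_diag}")


def sample_occurrences(
    species: VirtualSpecies,
    stack: EnvStack,
    polygon: BaseGeometry,
    n: int,
    completeness: float = 1.0,
    bias: str = "none",
    seed: int | np.random.Generator = 0,
    core_fraction: float = 0.95,
    core_width_frac: float = 0.25,
) -> np.ndarray:
    """Sample occurrence points from the suitable cells inside a polygon.

    Suitable cells are those whose (standardised) values fall inside the
    species' niche box; one uniformly placed point is drawn per chosen cell.
    ``completeness`` < 1 truncates each niche-box axis to that fraction of
    its width (anchored at the low end) before sampling, emulating an
    unsampled portion of the niche. Bias modes: ``none`` (uniform over
    suitable cells), ``spatial-cluster`` (a ``core_fraction`` share of
    records drawn from a narrow stripe of cells around the polygon's center
    along the dominant gradient, the rest uniform), or
    ``environmental-truncation`` (alias for uniform sampling of the
    truncated box; requires completeness < 1).
    """
    if not 0 < completeness <= 1:
        raise ValueError("completeness must be in (0, 1]")
    if bias == "environmental-truncation" and completeness >= 1:
        raise ValueError("environmental-truncation bias requires completeness < 1")
    if bias not in {"none", "spatial-cluster", "environmental-truncation"}:
        raise ValueError(f"unknown bias mode {bias!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    box = {
        name: (lo, lo + completeness * (hi - lo))
        for name, (lo, hi) in species.niche_box.items()
    }
    trunc = VirtualSpecies(box, logistic_width=species.logistic_width)

    nrows, ncols = stack.shape
    ref = stack.layers[0]
    lons = np.array([ref.cell_center(0, c)[0] for c in range(ncols)])
    lats = np.array([ref.cell_center(r, 0)[1] for r in range(nrows)])
    LON, LAT = np.meshgrid(lons, lats)
    inside = shapely.contains_xy(polygon, LON.ravel(), LAT.ravel()).reshape(nrows, ncols)
    inside &= stack.valid_mask()
    values = np.stack([layer.values.data for layer in stack.layers], axis=-1)
    flat_ok = inside.ravel()
    suit = trunc.suitability(
        values.reshape(-1, len(stack.names)), stack.names, rng=rng
    )
    cand = np.flatnonzero(flat_ok & suit)
    if cand.size == 0:
        raise ValueError("no suitable cells inside the polygon")
    n_eff = min(n, cand.size)
    if n_eff < n:
        warnings.warn(
            f"only {cand.size} suitable cells available; sampling {n_eff} records",
            stacklevel=2,
        )
    if bias == "spatial-cluster":
        cand_lon = LON.ravel()[cand]
        cx = 0.5 * (cand_lon.min() + cand_lon.max())
        w = core_width_frac * (cand_lon.max() - cand_lon.min())
        n_core = int(round(core_fraction * n_eff))
        # core stripe around the center column, widened just enough to hold
        # the core share when the polygon is small
        order = np.argsort(np.abs(cand_lon - cx), kind="stable")
        in_stripe = np.abs(cand_lon - cx) <= w / 2
        pool_size = max(int(in_stripe.sum()), min(cand.size, int(np.ceil(1.5 * n_core))))
        core = cand[order[:pool_size]]
        n_core = min(n_core, core.size)
        chosen_core = rng.choice(core, size=n_core, replace=False)
        rest_pool = np.setdiff1d(cand, chosen_core)
        n_rest = min(n_eff - n_core, rest_pool.size)
        chosen = np.concatenate(
            [chosen_core, rng.choice(rest_pool, size=n_rest, replace=False)]
        )
    else:
        chosen = rng.choice(cand, size=n_eff, replace=False)
    rows, cols = np.unravel_index(chosen, (nrows, ncols))
    cs = stack.cell_size
    pts = np.empty((chosen.size, 2))
    for i, (r, c) in enumerate(zip(rows, cols)):
        clon, clat = ref.cell_center(int(r), int(c))
        pts[i] = (
            clon + rng.uniform(-cs / 2, cs / 2),
            clat + rng.uniform(-cs / 2, cs / 2),
        )
    return pts


# ---------------------------------------------------------------------------
# Scenario presets


@dataclass(frozen=True)
class ScenarioPreset:
    """Knob settings that reproduce one designed outcome scenario."""

    label: str
    native_n: int = 200
    native_bias: str = "none"  # none | spatial-cluster
    records_per_region: int = 30
    n_regions: int = 10
    layout: str = "novel"
    occupancy: float = 0.6  # fraction of the alien block's gradient span the species tolerates
    n_cols: int = 100
    n_rows: int = 100
    smoothness: float = 0.02
    completeness: float = 1.0
    species_name: str = "Virtualis exempli"


PRESETS: dict[str, ScenarioPreset] = {
    "a": ScenarioPreset(label="a"),
    "b": ScenarioPreset(label="b", native_bias="spatial-cluster"),
    "c": ScenarioPreset(label="c", layout="two-sided", occupancy=0.96),
    "d": ScenarioPreset(
        label="d", native_bias="spatial-cluster", layout="two-sided", occupancy=0.96
    ),
    "nested": ScenarioPreset(
        label="nested", layout="nested", n_regions=8, records_per_region=20
    ),
}


@dataclass
class ScenarioBundle:
    """A complete, self-consistent input set for one pipeline run."""

    preset: ScenarioPreset
    stack: EnvStack
    native_polygon: BaseGeometry
    regions: RegionSet
    occurrences: pd.DataFrame  # species, decimalLongitude, decimalLatitude
    checklist: list[str]
    species: VirtualSpecies
    seed: int = 0
    designed_scenario: str = ""


def _gradient_anchor(stack: EnvStack, layer_name: str, frac: float, axis: str) -> float:
    """Mean standardised value of a layer along one column (axis='x') or row."""
    layer = stack[layer_name]
    nrows, ncols = layer.shape
    if axis == "x":
        c = min(int(frac * ncols), ncols - 1)
        return float(np.mean(layer.values.data[:, c]))
    r = nrows - 1 - min(int(frac * nrows), nrows - 1)
    return float(np.mean(layer.values.data[r, :]))


def make_scenario(preset: ScenarioPreset | str, seed: int = 0) -> ScenarioBundle:
    """Build the full input bundle for one designed outcome scenario.

    The landscape has two orthogonal gradient layers (east-west and
    north-south) plus a third collinear blend that exercises the
    collinearity filter. The species' tolerance box is anchored to the
    gradients so that the native/alien/background geometry realises the
    preset's outcome (see the module docstring for the per-scenario logic).
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    rng = np.random.default_rng(seed)
    folded = preset.layout == "nested"
    stack = generate_stack(
        n_cols=preset.n_cols,
        n_rows=preset.n_rows,
        k_vars=2,
        smoothness=preset.smoothness,
        seed=rng,
        names=["bio1", "bio2", "bio3"],
        mixing=np.array([[1.0, 0.0], [0.0, 1.0], [0.75, 0.66]]),
        rotation=0.0,
        folded=folded,
    )
    native, regions = generate_regions(
        stack, layout=preset.layout, seed=rng, m=preset.n_regions
    )
    if folded:
        # tolerance box: slightly inset native environment, so the mirrored
        # alien regions are strictly nested inside it
        x_lo, x_hi = 0.0875, 0.3625
        y_lo, y_hi = 0.175, 0.825
    elif preset.layout == "two-sided":
        # tolerance reaches 'occupancy' of the way across both the east and
        # the north alien blocks, so (nearly) every region slice offers
        # conditions the species can occupy
        x_lo, x_hi = 0.125, 0.3 + preset.occupancy * (0.95 - 0.3)
        y_lo, y_hi = 0.075, 0.55 + preset.occupancy * (0.95 - 0.55)
    else:
        # east-west tolerance runs from inside the native range to 'occupancy'
        # of the way across the alien block (block spans fractions 0.3-0.95);
        # north-south tolerance exceeds both ranges so the designed novelty
        # axis is the dominant east-west gradient
        x_lo, x_hi = 0.125, 0.3 + preset.occupancy * (0.95 - 0.3)
        y_lo, y_hi = 0.075, 0.925
    niche_box = {
        "bio1": tuple(sorted((
            _gradient_anchor(stack, "bio1", x_lo, "x"),
            _gradient_anchor(stack, "bio1", x_hi, "x"),
        ))),
        "bio2": tuple(sorted((
            _gradient_anchor(stack, "bio2", y_lo, "y"),
            _gradient_anchor(stack, "bio2", y_hi, "y"),
        ))),
    }
    species = VirtualSpecies(niche_box)

    native_pts = sample_occurrences(
        species,
        stack,
        native,
        n=preset.native_n,
        completeness=preset.completeness,
        bias=preset.native_bias,
        seed=rng,
    )
    alien_pts = []
    for rid in sorted(regions.regions):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # partially suitable regions
                alien_pts.append(
                    sample_occurrences(
                        species, stack, regions.regions[rid],
                        n=preset.records_per_region, seed=rng,
                    )
                )
        except ValueError:
            pass  # region offers no suitable conditions; stays in the checklist
    pts = np.vstack([native_pts] + alien_pts)
    occurrences = pd.DataFrame(
        {
            "species": preset.species_name,
            "decimalLongitude": pts[:, 0],
            "decimalLatitude": pts[:, 1],
        }
    )
    designed = "a" if preset.label == "nested" else preset.label
    return ScenarioBundle(
        preset=preset,
        stack=stack,
        native_polygon=native,
        regions=regions,
        occurrences=occurrences,
        checklist=sorted(regions.regions),
        species=species,
        seed=seed,
        designed_scenario=designed,
    )


def write_bundle(bundle: ScenarioBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle in the pipeline's external formats.

    Produces ``stack/`` (.asc + sidecar), ``native_range.geojson`` (with a
    ``legend`` status attribute), ``regions.geojson``, ``occurrences.csv``
    and ``checklist.csv``; returns the paths keyed by role.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": outdir / "stack",
        "ranges": outdir / "native_range.geojson",
        "regions": outdir / "regions.geojson",
        "occurrences": outdir / "occurrences.csv",
        "checklist": outdir / "checklist.csv",
    }
    write_stack(bundle.stack, paths["stack"])
    paths["ranges"].write_text(
        json.dumps(
            {
                "type": "FeatureCollection",
                "features": [
                    {
                        "type": "Feature",
                        "properties": {"legend": "Native"},
                        "geometry": shapely_mapping(bundle.native_polygon),
                    }
                ],
            }
        )
    )
    paths["regions"].write_text(
        json.dumps(
            {
                "type": "FeatureCollection",
                "features": [
                    {
                        "type": "Feature",
                        "properties": {"region_id": rid},
                        "geometry": shapely_mapping(geom),
                    }
                    for rid, geom in sorted(bundle.regions.regions.items())
                ],
            }
        )
    )
    bundle.occurrences.to_csv(paths["occurrences"], index=False)
    pd.DataFrame(
        {"species": bundle.preset.species_name, "region_id": bundle.checklist}
    ).to_csv(paths["checklist"], index=False)
    return paths
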