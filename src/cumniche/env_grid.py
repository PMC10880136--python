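"""Environmental raster grids: containers, standardisation, point extraction.

All grids are geographic (lon/lat, WGS84), axis-aligned with square cells.
Layers in a stack must already be co-registered: same origin, cell size and
dimensions. Rasters are read and written as ESRI ASCII grids (``.asc``), the
plain-text raster format traditional in species distribution modelling, with
a JSON sidecar carrying layer order and standardisation parameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GridSpec",
    "EnvLayer",
    "EnvStack",
    "StandardizationParams",
    "standardize_stack",
    "extract_values",
    "cell_id",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "write_stack",
]


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid anchored at a fixed origin.

    Used both for the occurrence-thinning grid (2.5 arc-minutes by default
    upstream) and the coarser background-sampling grid (0.25 degrees). The
    origin anchors cell edges; cells are half-open ``[edge, edge + size)``.
    """

    cell_size: float
    origin: tuple[float, float] = (-180.0, -90.0)

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")


def cell_id(lon: float, lat: float, grid: GridSpec) -> tuple[int, int]:
    """Return the (col, row) index of the grid cell containing a point.

    ``col = floor((lon - origin_lon) / cell_size)`` and likewise for rows.
    Deterministic; every finite point maps to exactly one cell.
    """
    if not (np.isfinite(lon) and np.isfinite(lat)):
        raise ValueError("coordinates must be finite")
    col = int(np.floor((lon - grid.origin[0]) / grid.cell_size))
    row = int(np.floor((lat - grid.origin[1]) / grid.cell_size))
    return col, row


@dataclass
class EnvLayer:
    """One environmental variable on a regular lon/lat grid.

    ``values`` is a 2-D masked array with row 0 at the *northern* edge
    (raster convention); ``origin`` is the lower-left corner of the grid.
    """

    name: str
    values: np.ma.MaskedArray
    origin: tuple[float, float]
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.ma.masked_invalid(np.ma.asarray(self.values, dtype=float))
        if self.values.ndim != 2 or 0 in self.values.shape:
            raise ValueError(f"layer {self.name!r}: values must be a non-empty 2-D grid")
        if not self.cell_size > 0:
            raise ValueError(f"layer {self.name!r}: cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_lon, min_lat, max_lon, max_lat) of the raster extent."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + ncols * self.cell_size, y0 + nrows * self.cell_size)

    def rowcol(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Array (row, col) of the cell containing the point, or None if outside.

        Cells are half-open lower-left closed; points exactly on the top or
        right edge are assigned to the last cell.
        """
        nrows, ncols = self.values.shape
        xmin, ymin, xmax, ymax = self.bounds
        if not (xmin <= lon <= xmax and ymin <= lat <= ymax):
            return None
        col = min(int(np.floor((lon - xmin) / self.cell_size)), ncols - 1)
        row_s = min(int(np.floor((lat - ymin) / self.cell_size)), nrows - 1)
        return nrows - 1 - row_s, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrows = self.values.shape[0]
        lon = self.origin[0] + (col + 0.5) * self.cell_size
        lat = self.origin[1] + (nrows - 1 - row + 0.5) * self.cell_size
        return lon, lat


@dataclass(frozen=True)
class StandardizationParams:
    """Per-layer mean and standard deviation used to z-score a stack.

    ``ddof`` records the denominator convention (1 = sample sd, the default)
    so either convention can be replayed exactly.
    """

    means: dict[str, float]
    sds: dict[str, float]
    ddof: int = 1

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"layer {name!r}: sd must be positive, got {sd}")

    def to_dict(self) -> dict:
        return {"means": dict(self.means), "sds": dict(self.sds), "ddof": self.ddof}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(means=dict(d["means"]), sds=dict(d["sds"]), ddof=int(d.get("ddof", 1)))


@dataclass
class EnvStack:
    """An ordered collection of co-registered environmental layers."""

    layers: list[EnvLayer]
    standardization: StandardizationParams | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack must contain at least one layer")
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"layer names must be unique, got {names}")
        ref = self.layers[0]
        for layer in self.layers[1:]:
            if (
                layer.shape != ref.shape
                or layer.origin != ref.origin
                or layer.cell_size != ref.cell_size
            ):
                raise ValueError(
                    f"layer {layer.name!r} is not co-registered with {ref.name!r}"
                )

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].shape

    @property
    def cell_size(self) -> float:
        return self.layers[0].cell_size

    @property
    def origin(self) -> tuple[float, float]:
        return self.layers[0].origin

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.layers[0].bounds

    def __getitem__(self, name: str) -> EnvLayer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)

    def select(self, names: list[str]) -> "EnvStack":
        """Sub-stack keeping only the named layers, in the given order."""
        std = None
        if self.standardization is not None:
            std = StandardizationParams(
                means={n: self.standardization.means[n] for n in names},
                sds={n: self.standardization.sds[n] for n in names},
                ddof=self.standardization.ddof,
            )
        return EnvStack([self[n] for n in names], standardization=std)

    def valid_mask(self) -> np.ndarray:
        """Boolean grid: True where every layer has data."""
        ok = ~np.ma.getmaskarray(self.layers[0].values)
        for layer in self.layers[1:]:
            ok &= ~np.ma.getmaskarray(layer.values)
        return ok


def standardize_stack(
    stack: EnvStack, params: StandardizationParams | None = None, ddof: int = 1
) -> tuple[EnvStack, StandardizationParams]:
    """Z-score every layer: ``(val - mean) / sd`` over its non-masked cells.

    The mean and sd are computed per layer over non-masked cells only (sample
    sd, ``ddof=1``, by default). Passing ``params`` applies stored parameters
    instead of re-estimating, so a standardised stack can be reproduced
    bit-for-bit from the raw stack.

    Returns the standardised stack and the parameters used.

    Raises
    ------
    ValueError
        If a layer is constant (sd = 0) or entirely masked.
    """
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    out_layers = []
    for layer in stack.layers:
        data = layer.values.compressed()
        if data.size == 0:
            raise ValueError(f"layer {layer.name!r} is entirely masked")
        if params is not None:
            mu, sd = params.means[layer.name], params.sds[layer.name]
            ddof = params.ddof
        else:
            if data.size < 2 or np.unique(data).size < 2:
                raise ValueError(
                    f"constant layer {layer.name!r}: cannot standardise (sd = 0)"
                )
            mu = float(np.mean(data))
            sd = float(np.std(data, ddof=ddof))
            if sd == 0:
                raise ValueError(
                    f"constant layer {layer.name!r}: cannot standardise (sd = 0)"
                )
        means[layer.name] = mu
        sds[layer.name] = sd
        out_layers.append(
            EnvLayer(
                name=layer.name,
                values=(layer.values - mu) / sd,
                origin=layer.origin,
                cell_size=layer.cell_size,
            )
        )
    used = params if params is not None else StandardizationParams(means, sds, ddof=ddof)
    return EnvStack(out_layers, standardization=used), used


def extract_values(
    stack: EnvStack, points: np.ndarray | list[tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Sample every layer of the stack at a list of lon/lat points.

    Returns ``(matrix, kept)`` where ``matrix`` has one row per surviving
    point (input order preserved) and one column per layer, and ``kept`` is
    the integer index of the surviving points in the input. Points outside
    the raster extent or on a nodata cell in any layer are dropped (with a
    warning for out-of-extent points), never raised on.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    rows_out: list[list[float]] = []
    kept: list[int] = []
    n_outside = 0
    ref = stack.layers[0]
    for i, (lon, lat) in enumerate(pts):
        rc = ref.rowcol(lon, lat)
        if rc is None:
            n_outside += 1
            continue
        r, c = rc
        vals = [layer.values[r, c] for layer in stack.layers]
        if any(v is np.ma.masked for v in vals):
            continue
        rows_out.append([float(v) for v in vals])
        kept.append(i)
    if n_outside:
        warnings.warn(
            f"{n_outside} point(s) outside raster extent were dropped", stacklevel=2
        )
    matrix = np.asarray(rows_out, dtype=float).reshape(len(kept), len(stack.layers))
    return matrix, np.asarray(kept, dtype=int)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_NODATA = -9999.0


def write_ascii_grid(layer: EnvLayer, path: str | Path) -> None:
    """Write one layer as an ESRI ASCII grid (.asc)."""
    path = Path(path)
    nrows, ncols = layer.shape
    filled = layer.values.filled(_NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {layer.origin[0]!r}\n")
        fh.write(f"yllcorner {layer.origin[1]!r}\n")
        fh.write(f"cellsize {layer.cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA}\n")
        np.savetxt(fh, filled, fmt="%.17g")


def read_ascii_grid(path: str | Path, name: str | None = None) -> EnvLayer:
    """Read an ESRI ASCII grid (.asc) into an EnvLayer."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", _NODATA)
    values = np.ma.masked_values(data, nodata)
    return EnvLayer(
        name=name or path.stem,
        values=values,
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
    )


def write_stack(stack: EnvStack, directory: str | Path) -> None:
    """Write a stack as one .asc per layer plus a ``stack.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for layer in stack.layers:
        write_ascii_grid(layer, directory / f"{layer.name}.asc")
    sidecar = {
        "layers": stack.names,
        "standardization": (
            stack.standardization.to_dict() if stack.standardization else None
        ),
    }
    (directory / "stack.json").write_text(json.dumps(sidecar, indent=2))


def read_stack(directory: str | Path) -> EnvStack:
    """Read a stack written by :func:`write_stack`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "stack.json").read_text())
    layers = [read_ascii_grid(directory / f"{n}.asc", name=n) for n in sidecar["layers"]]
    std = sidecar.get("standardization")
    return EnvStack(
        layers,
        standardization=StandardizationParams.from_dict(std) if std else None,
    )
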