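"""Niche breadth as a multiplicative range product in standardised space.

The breadth of a point cloud over k selected (standardised) environmental
variables is B = prod_j A_j, where A_j = max_j - min_j is the amplitude of
variable j across the points. B estimates the volume of the axis-aligned
environmental box occupied by the species; it is zero for fewer than two
environmentally distinct points and never decreases as points are added.

Extrema are carried exactly (per-variable min/max), so incremental updates
are bitwise identical to a single batch computation regardless of order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NicheBreadth", "breadth_from_points", "update", "breadth_ratio"]


@dataclass(frozen=True)
class NicheBreadth:
    """Per-variable amplitudes and their product for one point cloud."""

    variables: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    n_points: int

    @property
    def amplitudes(self) -> np.ndarray:
        return self.maxs - self.mins

    @property
    def breadth(self) -> float:
        return float(np.prod(self.amplitudes))


def breadth_from_points(
    values: np.ndarray, variables: list[str] | tuple[str, ...] | None = None
) -> NicheBreadth:
    """Niche breadth of a point × variable matrix of standardised values.

    A single point has zero amplitude on every axis, hence breadth zero.

    Raises
    ------
    ValueError
        On an empty matrix, an empty variable set, or non-finite values.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        values = values.reshape(-1, values.shape[-1]) if values.size else values
    if values.size == 0 or values.ndim != 2 or values.shape[1] == 0:
        raise ValueError("breadth requires at least 1 point and 1 variable")
    if not np.all(np.isfinite(values)):
        raise ValueError("breadth requires finite values")
    k = values.shape[1]
    if variables is None:
        variables = tuple(f"v{i}" for i in range(k))
    if len(variables) != k:
        raise ValueError("variable names do not match matrix columns")
    return NicheBreadth(
        variables=tuple(variables),
        mins=values.min(axis=0),
        maxs=values.max(axis=0),
        n_points=values.shape[0],
    )


def update(state: NicheBreadth, new_values: np.ndarray) -> NicheBreadth:
    """Fold new points into an existing breadth state.

    Identical (bitwise on extrema) to recomputing from the concatenated point
    set. An empty matrix leaves the state unchanged.
    """
    new_values = np.asarray(new_values, dtype=float)
    if new_values.size == 0:
        return state
    if new_values.ndim == 1:
        new_values = new_values.reshape(1, -1)
    if new_values.shape[1] != len(state.variables):
        raise ValueError(
            f"column mismatch: state has {len(state.variables)} variables, "
            f"update has {new_values.shape[1]}"
        )
    if not np.all(np.isfinite(new_values)):
        raise ValueError("breadth requires finite values")
    return NicheBreadth(
        variables=state.variables,
        mins=np.minimum(state.mins, new_values.min(axis=0)),
        maxs=np.maximum(state.maxs, new_values.max(axis=0)),
        n_points=state.n_points + new_values.shape[0],
    )


def breadth_ratio(accumulated: NicheBreadth, reference: NicheBreadth) -> float:
    """Ratio of an accumulated breadth to a reference breadth.

    Raises
    ------
    ValueError
        If the reference breadth is zero (the species has fewer than two
        environmentally distinct records on some variable); the offending
        variables are named.
    """
    if reference.breadth <= 0:
        flat = [
            v for v, a in zip(reference.variables, reference.amplitudes) if a == 0
        ]
        raise ValueError(
            "reference niche breadth is zero; species has < 2 environmentally "
            f"distinct records on variable(s): {flat}"
        )
    return accumulated.breadth / reference.breadth
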