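"""Asymptote detection, outcome classification and sampling-bias screening.

The curves themselves carry no verdict; "approaching an asymptote" is
operationalised here with a dual criterion on the mean curve: (1) the curve
must reach 95% of its total rise within the first half of its steps, and
(2) the tail (final 20% of steps) must be nearly flat (mean per-step
increase at most 1% of the total rise). Both thresholds are configurable
and recorded in the run manifest. The total rise is measured from the
curve's conceptual origin — 0 for the native curve (no folds, no breadth),
1 for alien/background curves (no regions, native breadth).

The four outcome scenarios form a 2×2 over the native and alien verdicts:

  a. both reached — niche comparison and projection both trustworthy;
  b. alien reached only — projection trustworthy, comparison not;
  c. native reached only — comparison trustworthy, projection not;
  d. neither reached.

A reached alien curve is only meaningful when the background curve shows
*headroom* — conditions in the invaded regions that would have allowed more
expansion than observed. Without headroom the flatness merely reflects
environmental nestedness, so the alien verdict is demoted to
"uninformative-nested" and projection confidence drops to low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accumulation import Curve, native_curve
from .niche_breadth import breadth_from_points

__all__ = [
    "AsymptoteConfig",
    "AsymptoteVerdict",
    "CNAOutcome",
    "detect_asymptote",
    "classify_outcome",
    "bias_screen",
    "BiasScreenReport",
]

HIGH = "high"
LOW = "low"


@dataclass(frozen=True)
class AsymptoteConfig:
    rise_threshold: float = 0.95
    max_fraction: float = 0.5
    tail_slope_max: float = 0.01
    tail_window: float = 0.2


@dataclass(frozen=True)
class AsymptoteVerdict:
    reached: bool
    fraction_at_95: float
    tail_slope: float
    undetermined: bool = False

    def to_dict(self) -> dict:
        return {
            "reached": self.reached,
            "fraction_at_95": self.fraction_at_95,
            "tail_slope": self.tail_slope,
            "undetermined": self.undetermined,
        }


def detect_asymptote(
    curve: Curve,
    rise_threshold: float = 0.95,
    max_fraction: float = 0.5,
    tail_slope_max: float = 0.01,
    tail_window: float = 0.2,
) -> AsymptoteVerdict:
    """Judge whether a mean accumulation curve approaches an asymptote.

    ``fraction_at_95`` is the fraction of steps needed for the mean curve to
    first cover ``rise_threshold`` of its total rise (origin → final value);
    ``tail_slope`` is the mean per-step increase over the final
    ``tail_window`` of steps, relative to the total rise. The curve is
    *reached* when ``fraction_at_95 <= max_fraction`` and
    ``tail_slope <= tail_slope_max``. A flat curve (zero rise, e.g. an alien
    curve stuck at 1) counts as reached with ``fraction_at_95 = 1/n``.

    Curves with fewer than 3 steps return an *undetermined* verdict (treated
    as not reached).
    """
    y = curve.mean
    n = y.size
    if n < 3:
        return AsymptoteVerdict(
            reached=False, fraction_at_95=1.0, tail_slope=0.0, undetermined=True
        )
    rise = float(y[-1] - curve.origin)
    if rise < 0:
        raise ValueError("accumulation curve cannot end below its origin")
    if rise == 0:
        return AsymptoteVerdict(reached=True, fraction_at_95=1.0 / n, tail_slope=0.0)
    covered = (y - curve.origin) / rise
    first = int(np.argmax(covered >= rise_threshold)) + 1  # 1-based step index
    fraction = first / n
    n_tail = max(1, int(np.ceil(tail_window * n)))
    tail = y[-(n_tail + 1):]
    tail_slope = float(np.mean(np.diff(tail))) / rise if tail.size >= 2 else 0.0
    tail_slope = max(0.0, tail_slope)
    reached = fraction <= max_fraction and tail_slope <= tail_slope_max
    return AsymptoteVerdict(reached=reached, fraction_at_95=fraction, tail_slope=tail_slope)


@dataclass
class CNAOutcome:
    scenario: str
    niche_comparison_confidence: str
    projection_confidence: str
    background_headroom: bool
    expansion_ratio: float
    nested: bool = False
    notes: list[str] = field(default_factory=list)
    native_verdict: AsymptoteVerdict | None = None
    alien_verdict: AsymptoteVerdict | None = None
    background_verdict: AsymptoteVerdict | None = None

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "niche_comparison_confidence": self.niche_comparison_confidence,
            "projection_confidence": self.projection_confidence,
            "background_headroom": self.background_headroom,
            "expansion_ratio": self.expansion_ratio,
            "nested": self.nested,
            "notes": list(self.notes),
            "native_verdict": self.native_verdict.to_dict() if self.native_verdict else None,
            "alien_verdict": self.alien_verdict.to_dict() if self.alien_verdict else None,
            "background_verdict": (
                self.background_verdict.to_dict() if self.background_verdict else None
            ),
        }

    def summary(self) -> str:
        lines = [
            f"scenario: {self.scenario}",
            f"niche comparison confidence: {self.niche_comparison_confidence}",
            f"projection confidence: {self.projection_confidence}",
            f"expansion ratio (alien final mean): {self.expansion_ratio:.3f}",
            f"background headroom: {self.background_headroom}",
        ]
        if self.nested:
            lines.append(
                "WARNING: alien regions are environmentally nested in the native "
                "envelope; the flat alien curve is uninformative"
            )
        lines.extend(self.notes)
        return "\n".join(lines)


def classify_outcome(
    native: AsymptoteVerdict,
    alien: AsymptoteVerdict,
    background: Curve,
    alien_curve: Curve,
    headroom_margin: float = 0.05,
) -> CNAOutcome:
    """Combine the three curves into one of the four outcome scenarios.

    The scenario letter follows the native/alien asymptote 2×2 (a: both,
    b: alien only, c: native only, d: neither). Background headroom —
    the background curve ending more than ``headroom_margin`` (relative)
    above the alien curve — guards the alien verdict: a reached alien curve
    without headroom is demoted to uninformative (environmental nestedness)
    and projection confidence is set low.
    """
    alien_final = alien_curve.final_mean
    bg_final = background.final_mean
    headroom = (bg_final - alien_final) / alien_final > headroom_margin

    scenario = {
        (True, True): "a",
        (False, True): "b",
        (True, False): "c",
        (False, False): "d",
    }[(native.reached, alien.reached)]
    comparison = HIGH if native.reached else LOW
    projection = HIGH if alien.reached else LOW
    nested = False
    notes = []
    if alien.reached and not headroom:
        nested = True
        projection = LOW
        notes.append(
            "alien curve reached an asymptote but the background offers no "
            "headroom: flatness reflects environmental nestedness, not the "
            "species' tolerance limits (alien verdict uninformative-nested)"
        )
    if native.undetermined or alien.undetermined:
        notes.append("a curve had fewer than 3 steps; its verdict is undetermined")
    return CNAOutcome(
        scenario=scenario,
        niche_comparison_confidence=comparison,
        projection_confidence=projection,
        background_headroom=headroom,
        expansion_ratio=alien_final,
        nested=nested,
        notes=notes,
        native_verdict=native,
        alien_verdict=alien,
        background_verdict=detect_asymptote(background),
    )


@dataclass
class BiasScreenReport:
    breadth_ratio: float
    flagged: bool
    mode: str
    reference_breadth: float
    focal_breadth: float
    reference_curve: Curve | None = None

    def to_dict(self) -> dict:
        return {
            "breadth_ratio": self.breadth_ratio,
            "flagged": self.flagged,
            "mode": self.mode,
            "reference_breadth": self.reference_breadth,
            "focal_breadth": self.focal_breadth,
        }


def bias_screen(
    focal_curve: Curve,
    reference_values: np.ndarray,
    mode: str = "stratified_random",
    narrow_fraction: float = 0.5,
    n_reps: int = 10,
    rng_seed: int = 0,
) -> BiasScreenReport:
    """Screen a focal species' curve against a reference point set.

    Builds a reference accumulation curve from the supplied locations
    (stratified-random samples or a broader reference species group) and
    compares asymptotic breadths. When the focal breadth is below
    ``narrow_fraction`` of the reference breadth, the focal asymptote may
    only reflect the well-sampled portion of the niche and is flagged.
    """
    reference_values = np.asarray(reference_values, dtype=float)
    if reference_values.size == 0:
        raise ValueError("reference point set is empty")
    if mode not in {"stratified_random", "reference_group"}:
        raise ValueError(f"unknown bias-screen mode {mode!r}")
    ref_breadth = breadth_from_points(reference_values).breadth
    if ref_breadth <= 0:
        raise ValueError("reference point set has zero breadth")
    ref_curve = native_curve(reference_values, n_reps=n_reps, rng_seed=rng_seed)
    ratio = focal_curve.total_breadth / ref_breadth
    return BiasScreenReport(
        breadth_ratio=ratio,
        flagged=ratio < narrow_fraction,
        mode=mode,
        reference_breadth=ref_breadth,
        focal_breadth=focal_curve.total_breadth,
        reference_curve=ref_curve,
    )
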