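"""Step-wise HU-to-mass-density override.

CBCT intensity values are unreliable for dose computation, so both the
planning CT and every CBCT are collapsed onto a small set of density levels
(air, lung, adipose/soft tissue, cartilage/bone, prosthesis) before any dose
or registration step.  Applying the *same* table to both sides puts the
conversion error into planned and delivered dose alike, which keeps the two
comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .core import ScalarVolume


@dataclass(frozen=True)
class DensityStep:
    """One HU interval ``[lower, upper)`` mapped to a constant density."""

    lower: float  # HU, inclusive
    upper: float  # HU, exclusive
    density: float  # g/cm^3
    label: str = ""


@dataclass
class DensityTable:
    """Ordered, contiguous, half-open HU intervals with increasing density.

    Intervals are closed below and open above, so an HU value exactly on a
    breakpoint belongs to the upper interval.
    """

    steps: Tuple[DensityStep, ...]

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        if len(steps) < 2:
            raise ValueError("a density table needs at least two steps")
        if steps[0].lower != -np.inf or steps[-1].upper != np.inf:
            raise ValueError("steps must cover the full HU axis")
        for a, b in zip(steps, steps[1:]):
            if a.upper != b.lower:
                raise ValueError("steps must be contiguous and non-overlapping")
            if not a.density < b.density:
                raise ValueError("densities must strictly increase with HU")
        for s in steps:
            if not (np.isfinite(s.density) and s.density > 0):
                raise ValueError("densities must be positive and finite")
        self.steps = steps

    # internal breakpoints between consecutive steps, ascending
    @property
    def breakpoints(self) -> np.ndarray:
        return np.array([s.lower for s in self.steps[1:]], dtype=np.float64)

    @property
    def densities(self) -> np.ndarray:
        return np.array([s.density for s in self.steps], dtype=np.float64)

    def lookup(self, hu) -> np.ndarray:
        """Vectorized density lookup; boundary HU goes to the upper interval."""
        hu = np.asarray(hu)
        if not np.isfinite(hu).all():
            raise ValueError("non-finite HU values cannot be density-overridden")
        idx = np.searchsorted(self.breakpoints, hu, side="right")
        return self.densities[idx]

    # ---------------------------------------------------------------- JSON
    def to_json(self, path) -> None:
        payload = [
            {"lower": s.lower, "upper": s.upper, "density": s.density, "label": s.label}
            for s in self.steps
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DensityTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            tuple(
                DensityStep(float(d["lower"]), float(d["upper"]), float(d["density"]), d.get("label", ""))
                for d in payload
            )
        )


def default_density_table() -> DensityTable:
    """The five-level default table (breakpoints in HU, densities in g/cm^3)."""
    return DensityTable(
        (
            DensityStep(-np.inf, -850.0, 0.001, "air"),
            DensityStep(-850.0, -200.0, 0.26, "lung"),
            DensityStep(-200.0, 120.0, 1.00, "adipose/soft tissue"),
            DensityStep(120.0, 1200.0, 1.60, "cartilage/bone"),
            DensityStep(1200.0, np.inf, 4.50, "prosthesis"),
        )
    )


def apply_density_override(hu: ScalarVolume, table: DensityTable | None = None) -> ScalarVolume:
    """Map an HU volume to a piecewise-constant density volume (same lattice)."""
    if table is None:
        table = default_density_table()
    return hu.like(table.lookup(hu.data).astype(np.float32))
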