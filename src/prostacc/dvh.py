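"""Dose-volume histograms and the endpoint metrics D_Mean, D02%, D95%, D98%.

``Dx%`` is the minimum dose received by the hottest x% of the structure
volume, computed from the sorted voxel doses with linear interpolation
between order statistics (equivalently: the ``(100 - x)``-th linear-
interpolation percentile of the voxel doses).  Whole voxels carry equal
volume; masks are native-lattice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core import ScalarVolume, StructureSet

TARGET_METRICS = ("D98", "D02", "D95", "DMean")


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of the structure receiving >= dose."""

    dose_gy: np.ndarray  # ascending
    volume_fraction: np.ndarray  # non-increasing, starts at 1
    structure: str = ""
    total_volume_cm3: float = float("nan")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_gy": self.dose_gy, "volume_fraction": self.volume_fraction}
        )


@dataclass
class DoseMetrics:
    structure: str
    d_mean: float
    d02: float
    d95: float
    d98: float
    volume_cm3: float


def _masked_doses(dose: ScalarVolume, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise ValueError("mask and dose live on different lattices")
    if not mask.any():
        raise ValueError("empty structure mask")
    return dose.data[mask].astype(np.float64)


def cumulative_dvh(
    dose: ScalarVolume,
    mask: np.ndarray,
    bin_width_gy: float = 0.01,
    structure: str = "",
    voxel_volume_cm3: float | None = None,
) -> DVHCurve:
    """Histogram the voxel doses in ``mask`` and accumulate from above."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be > 0")
    vals = _masked_doses(dose, mask)
    top = float(vals.max())
    n_bins = int(np.ceil(top / bin_width_gy)) + 1
    edges = np.arange(n_bins + 1) * bin_width_gy
    hist, _ = np.histogram(vals, bins=edges)
    # fraction receiving >= left edge of each bin
    vf = 1.0 - np.concatenate(([0.0], np.cumsum(hist))) / vals.size
    if voxel_volume_cm3 is None:
        voxel_volume_cm3 = float(np.prod(dose.spacing)) / 1000.0
    return DVHCurve(
        dose_gy=edges,
        volume_fraction=vf,
        structure=structure,
        total_volume_cm3=vals.size * voxel_volume_cm3,
    )


def dose_metric(dose: ScalarVolume, mask: np.ndarray, metric: str) -> float:
    """Evaluate ``DMean`` or a ``D<x>`` percent-volume metric in Gy."""
    vals = _masked_doses(dose, mask)
    if metric == "DMean":
        return float(vals.mean())
    m = re.fullmatch(r"D(\d+(?:\.\d+)?)", metric)
    if not m:
        raise ValueError(f"unknown metric {metric!r}")
    x = float(m.group(1))
    if not 0 < x < 100:
        raise ValueError("Dx% requires 0 < x < 100")
    return float(np.quantile(vals, 1.0 - x / 100.0, method="linear"))


def metrics_for_structures(
    dose: ScalarVolume, structures: StructureSet, names: Iterable[str]
) -> list[DoseMetrics]:
    out = []
    for name in names:
        mask = structures[name]
        out.append(
            DoseMetrics(
                structure=name,
                d_mean=dose_metric(dose, mask, "DMean"),
                d02=dose_metric(dose, mask, "D02"),
                d95=dose_metric(dose, mask, "D95"),
                d98=dose_metric(dose, mask, "D98"),
                volume_cm3=structures.volume_cm3(name),
            )
        )
    return out
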