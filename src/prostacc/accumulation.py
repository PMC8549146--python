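"""Per-fraction dose mapping onto CT_ref and course-level accumulation.

For every fraction the workflow takes the fraction's source CBCT (the
acquired CBCT of that day, or the most recent earlier one when the day was
not imaged), density-overrides it, aligns it rigidly from the recorded
couch shift, computes the fractional dose on the aligned anatomy, registers
the aligned CBCT deformably to CT_ref, pulls the fractional dose back
through the resulting vector field, and finally sums all fractional doses
voxel by voxel on CT_ref.

Fractions sharing a source CBCT reuse the cached registration and dose --
their inputs are identical, so this is exactly what recomputation would
produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .core import DeformationField, ScalarVolume, StructureSet, warp_volume_data
from .density import DensityTable, apply_density_override
from .phantom import AIR_HU, Anatomy, FractionScenario
from .planning import (
    TreatmentPlan,
    build_target_volumes,
    compute_fraction_dose,
    shape_dose_per_fraction,
)
from .registration import RegistrationParams, apply_couch_shift, deformable_register


@dataclass
class FractionDoseRecord:
    """One fraction's dose on CT_ref and the CBCT it was derived from."""

    fraction_index: int
    source_index: int
    dose: ScalarVolume  # Gy, on CT_ref

    def __post_init__(self) -> None:
        if self.source_index > self.fraction_index:
            raise ValueError("source CBCT cannot postdate the fraction")
        if (self.dose.data < 0).any():
            raise ValueError("fractional dose must be non-negative")


@dataclass
class AccumulatedDose:
    """Course total on CT_ref plus the per-fraction records behind it."""

    total: ScalarVolume
    records: List[FractionDoseRecord]
    fields_by_source: Dict[int, DeformationField] = field(default_factory=dict)
    planned: Optional[ScalarVolume] = None
    targets: Optional[StructureSet] = None


def map_fraction_sources(acquired: Sequence[bool]) -> List[int]:
    """1-based source CBCT index per fraction (previous-CBCT substitution).

    An imaged fraction is its own source; an unimaged one falls back to the
    nearest earlier imaged fraction.
    """
    sources: List[int] = []
    last: Optional[int] = None
    for i, flag in enumerate(acquired, start=1):
        if flag:
            last = i
        if last is None:
            raise ValueError(
                f"fraction {i} has no CBCT and no earlier CBCT exists"
            )
        sources.append(last)
    return sources


def warp_dose(dose_on_cbct: ScalarVolume, dvf: DeformationField) -> ScalarVolume:
    """Pull the fraction dose back onto CT_ref: D_ref(x) = D_cbct(x + u(x))."""
    if dose_on_cbct.shape != dvf.shape:
        raise ValueError("dose and deformation field live on different lattices")
    if not np.any(dvf.disp):
        return dose_on_cbct.copy()
    data = warp_volume_data(dose_on_cbct.data, dvf.disp, dose_on_cbct.spacing, fill=0.0)
    return dose_on_cbct.like(data)


def accumulate_course(
    anatomy: Anatomy,
    scenarios: Sequence[FractionScenario],
    plan: TreatmentPlan,
    reg_params: Optional[RegistrationParams] = None,
    density_table: Optional[DensityTable] = None,
    targets: Optional[StructureSet] = None,
) -> AccumulatedDose:
    """Run the full dose-accumulation workflow for one patient's course."""
    if len(scenarios) != plan.n_fractions:
        raise ValueError(
            f"expected {plan.n_fractions} fraction scenarios, got {len(scenarios)}"
        )
    if targets is None:
        targets = build_target_volumes(anatomy.structures)
    ct_ref_density = apply_density_override(anatomy.hu, density_table)
    shape_dose = shape_dose_per_fraction(targets, plan)
    sources = map_fraction_sources([s.acquired for s in scenarios])

    dose_cache: Dict[int, ScalarVolume] = {}
    field_cache: Dict[int, DeformationField] = {}
    total = np.zeros(anatomy.hu.shape, dtype=np.float64)
    records: List[FractionDoseRecord] = []

    for f_idx, src in zip(range(1, plan.n_fractions + 1), sources):
        if src not in dose_cache:
            scen = scenarios[src - 1]
            try:
                assert scen.cbct is not None
                aligned = apply_couch_shift(scen.cbct, scen.couch_shift_mm, fill=AIR_HU)
                cbct_density = apply_density_override(aligned, density_table)
                frac_dose = compute_fraction_dose(
                    cbct_density, targets, plan, ct_ref_density, shape_dose=shape_dose
                )
                dvf = deformable_register(ct_ref_density, cbct_density, reg_params)
                dose_cache[src] = warp_dose(frac_dose, dvf)
                field_cache[src] = dvf
            except Exception as exc:  # pragma: no cover - diagnostic context
                raise RuntimeError(
                    f"dose accumulation failed at fraction {f_idx} (source CBCT {src})"
                ) from exc
        mapped = dose_cache[src]
        total += mapped.data
        records.append(FractionDoseRecord(f_idx, src, mapped))

    return AccumulatedDose(
        total=anatomy.hu.like(total),
        records=records,
        fields_by_source=field_cache,
        targets=targets,
    )
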