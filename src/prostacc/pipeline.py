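"""Cohort-level orchestration: simulate -> plan -> accumulate -> compare.

This is the programmatic surface the CLI, the analysis scripts and the test
suite all drive.  ``run_cohort`` produces a :class:`CohortResult` holding
per-patient planned/delivered endpoint metrics, the paired planned-vs-
delivered comparisons, the dorsal-vs-ventral group comparison of the
delivered lesion mean dose, and the pooled couch-shift summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .accumulation import AccumulatedDose, accumulate_course
from .density import DensityTable, apply_density_override
from .dvh import dose_metric
from .phantom import PatientSim, PhantomConfig, generate_cohort
from .planning import TreatmentPlan, build_target_volumes, compute_planned_dose
from .registration import RegistrationParams
from .stats import (
    GroupComparison,
    PairedComparison,
    ShiftSummary,
    classify_dil_sector,
    group_compare,
    paired_compare,
    shift_summary,
)

# Table-style endpoint set: full coverage metrics for targets, mean dose for OARs
TARGET_ENDPOINTS: Tuple[Tuple[str, str], ...] = tuple(
    (s, m)
    for s in ("PTV_DIL", "PTV_Boost", "PTV")
    for m in ("D98", "D02", "D95", "DMean")
)
OAR_ENDPOINTS: Tuple[Tuple[str, str], ...] = (
    ("rectum", "DMean"),
    ("bladder", "DMean"),
    ("femoral_head_L", "DMean"),
    ("femoral_head_R", "DMean"),
    ("penile_bulb", "DMean"),
)
ALL_ENDPOINTS = TARGET_ENDPOINTS + OAR_ENDPOINTS


@dataclass
class PatientResult:
    patient_id: int
    sector_true: str  # generator's placement ("PZpm"/"ventral")
    sector_classified: str  # geometric classifier output ("dorsal"/"ventral")
    metrics: pd.DataFrame  # structure, metric, planned_gy, delivered_gy
    shifts_mm: np.ndarray  # acquired fractions only, (n, 3)
    accumulated: Optional[AccumulatedDose] = None
    planned_total: Optional[object] = None


@dataclass
class CohortResult:
    patients: List[PatientResult]
    metrics: pd.DataFrame  # long format over all patients
    paired: List[PairedComparison]
    dil_location: Optional[GroupComparison]
    shifts: ShiftSummary
    dorsal_delivered_dmean: List[float] = field(default_factory=list)
    ventral_delivered_dmean: List[float] = field(default_factory=list)

    def paired_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.paired:
            rows.append(
                {
                    "endpoint": c.endpoint,
                    "n": c.n,
                    "planned_mean_gy": c.planned_mean,
                    "planned_sd_gy": c.planned_sd,
                    "delivered_mean_gy": c.delivered_mean,
                    "delivered_sd_gy": c.delivered_sd,
                    "test": c.test,
                    "p_value": c.p_value,
                    "mean_difference_gy": c.mean_difference,
                }
            )
        return pd.DataFrame(rows)


def run_patient(
    sim: PatientSim,
    plan: Optional[TreatmentPlan] = None,
    reg_params: Optional[RegistrationParams] = None,
    density_table: Optional[DensityTable] = None,
    keep_volumes: bool = False,
) -> PatientResult:
    """Plan, accumulate and extract endpoint metrics for one patient."""
    if plan is None:
        plan = TreatmentPlan(n_fractions=sim.config.n_fractions)
    targets = build_target_volumes(sim.anatomy.structures)
    ct_ref_density = apply_density_override(sim.anatomy.hu, density_table)
    planned = compute_planned_dose(ct_ref_density, targets, plan)
    acc = accumulate_course(
        sim.anatomy, sim.scenarios, plan, reg_params, density_table, targets=targets
    )

    rows = []
    for structure, metric in ALL_ENDPOINTS:
        mask = targets[structure]
        rows.append(
            {
                "structure": structure,
                "metric": metric,
                "planned_gy": dose_metric(planned, mask, metric),
                "delivered_gy": dose_metric(acc.total, mask, metric),
            }
        )
    shifts = np.array(
        [s.couch_shift_mm for s in sim.scenarios if s.acquired], dtype=np.float64
    )
    return PatientResult(
        patient_id=sim.seed,
        sector_true=sim.config.dil_sector,
        sector_classified=classify_dil_sector(targets),
        metrics=pd.DataFrame(rows),
        shifts_mm=shifts,
        accumulated=acc if keep_volumes else None,
        planned_total=planned if keep_volumes else None,
    )


def cohort_statistics(patients: Sequence[PatientResult]) -> CohortResult:
    """Aggregate per-patient metrics into the cohort-level statistical layer."""
    frames = []
    for p in patients:
        df = p.metrics.copy()
        df.insert(0, "patient", p.patient_id)
        df["sector"] = p.sector_classified
        frames.append(df)
    metrics = pd.concat(frames, ignore_index=True)

    paired: List[PairedComparison] = []
    if len(patients) >= 3:
        for structure, metric in ALL_ENDPOINTS:
            sel = metrics[(metrics.structure == structure) & (metrics.metric == metric)]
            paired.append(
                paired_compare(
                    sel.planned_gy.to_numpy(),
                    sel.delivered_gy.to_numpy(),
                    endpoint=f"{structure} {metric}",
                )
            )

    dil = metrics[(metrics.structure == "PTV_DIL") & (metrics.metric == "DMean")]
    dorsal = dil[dil.sector == "dorsal"].delivered_gy.to_numpy()
    ventral = dil[dil.sector == "ventral"].delivered_gy.to_numpy()
    dil_location = (
        group_compare(dorsal, ventral) if dorsal.size >= 2 and ventral.size >= 2 else None
    )

    all_shifts = np.concatenate([p.shifts_mm for p in patients], axis=0)
    return CohortResult(
        patients=list(patients),
        metrics=metrics,
        paired=paired,
        dil_location=dil_location,
        shifts=shift_summary(all_shifts),
        dorsal_delivered_dmean=list(dorsal),
        ventral_delivered_dmean=list(ventral),
    )


def run_cohort(
    n_patients: int,
    config: Optional[PhantomConfig] = None,
    plan: Optional[TreatmentPlan] = None,
    seed: int = 0,
    reg_params: Optional[RegistrationParams] = None,
    sectors: Optional[Sequence[str]] = None,
) -> CohortResult:
    """End-to-end synthetic study: cohort simulation through group statistics."""
    cohort = generate_cohort(n_patients, config=config, seed=seed, sectors=sectors)
    patients = [run_patient(sim, plan=plan, reg_params=reg_params) for sim in cohort]
    return cohort_statistics(patients)
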