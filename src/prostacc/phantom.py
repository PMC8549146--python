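"""Synthetic male-pelvis phantom cohort with known ground-truth motion.

The generator emulates, per patient, a planning CT with contoured prostate,
seminal vesicles, dominant intraprostatic lesion (DIL), rectum, bladder,
femoral heads and penile bulb, plus a 33-fraction course of CBCT-like
volumes.  Each acquired fraction differs from the reference by

* a smooth organ-filling deformation (radial scaling around the bladder and
  rectum centroids, Gaussian-windowed) plus a correlated prostate drift,
* a 3-DOF translational setup error (the recorded "couch shift"),
* additive Gaussian HU noise and a low-frequency multiplicative bias field.

Because the deformations are analytic, the ground-truth displacement field
is known in closed form on the lattice, which is what makes registration
validation possible downstream.

Imaging follows the clinical schedule: a CBCT on each of the first five
fractions, then one every third fraction (8, 11, ..., 32 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .core import (
    DeformationField,
    ScalarVolume,
    StructureSet,
    sample_at_voxel_coords,
    voxel_index_grid,
)

AIR_HU = -1000.0

# nominal tissue HU (piecewise constant; CBCT degradation is added on top)
HU_VALUES = {
    "body": 30.0,
    "bladder": 10.0,
    "rectum_lumen": -700.0,  # rectal gas: the intensity anchor next to the target
    "prostate": 45.0,
    "seminal_vesicles": 40.0,
    "dil": 50.0,
    "femoral_head": 700.0,
    "penile_bulb": 35.0,
}


class GeometryError(ValueError):
    """Raised when configured organ geometry is inconsistent (e.g. DIL outside prostate)."""


@dataclass
class PhantomConfig:
    """Geometry, motion and imaging parameters of the synthetic cohort.

    All lengths are mm.  ``couch_shift_sd_mm`` is per axis in the package's
    (LR, AP, SI) axis order; the defaults carry the observed per-axis
    spreads of clinical setup corrections (~2.7-2.9 mm).
    """

    shape: Tuple[int, int, int] = (96, 96, 64)
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)

    # organ geometry
    prostate_semiaxes_mm: Tuple[float, float, float] = (20.0, 18.0, 18.0)
    bladder_radius_mm: float = 18.0
    rectum_radius_mm: float = 11.0
    dil_radius_mm: float = 5.0
    dil_sector: str = "PZpm"  # "PZpm" (dorsal) or "ventral"
    dil_offset_fraction: float = 0.7  # AP offset of the DIL center as a fraction
    # of the prostate AP semi-axis (posterior for PZpm, anterior otherwise);
    # the default puts a dorsal lesion at the posterior capsule, adjacent to
    # the rectal wall, matching the clinical picture of a PZpm lesion

    # motion model
    fill_scale_sd: float = 0.2  # SD of the dimensionless radial scaling of
    # bladder/rectum filling per fraction (~2 mm SD of wall displacement)
    prostate_drift_sd_mm: float = 1.5
    rectum_prostate_coupling: float = 0.4  # fraction of the rectal radial
    # surface change transferred to prostate AP drift

    # setup and imaging degradation
    couch_shift_sd_mm: Tuple[float, float, float] = (2.9, 2.8, 2.7)  # (LR, AP, SI)
    cbct_noise_sd_hu: float = 15.0
    bias_amplitude_hu: float = 20.0

    # CBCT schedule: daily for the first ``schedule_daily`` fractions, then
    # every ``schedule_interval``-th fraction
    n_fractions: int = 33
    schedule_daily: int = 5
    schedule_interval: int = 3

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bladder_radius_mm",
            "rectum_radius_mm",
            "dil_radius_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(s <= 0 for s in self.prostate_semiaxes_mm):
            raise ValueError("prostate semi-axes must be strictly positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.dil_sector not in ("PZpm", "ventral"):
            raise ValueError("dil_sector must be 'PZpm' or 'ventral'")
        if min(self.n_fractions, self.schedule_daily, self.schedule_interval) < 1:
            raise ValueError("schedule parameters must be >= 1")
        for v in (self.fill_scale_sd, self.prostate_drift_sd_mm,
                  self.cbct_noise_sd_hu, self.bias_amplitude_hu):
            if v < 0:
                raise ValueError("motion/noise SDs must be non-negative")


class Anatomy(NamedTuple):
    """Reference planning-CT anatomy: HU volume plus structure masks."""

    hu: ScalarVolume
    structures: StructureSet


@dataclass
class FractionScenario:
    """One treatment fraction of one patient.

    ``cbct`` and ``ground_truth_field`` are present iff a CBCT was acquired
    on that fraction.  The ground-truth field maps reference coordinates to
    fraction coordinates (pull-back convention), i.e. it is the field an
    ideal registration of the couch-shift-aligned CBCT to the reference
    would return.
    """

    fraction_index: int  # 1-based
    acquired: bool
    couch_shift_mm: np.ndarray  # (3,) recorded setup correction (LR, AP, SI)
    ground_truth_field: Optional[DeformationField] = None
    cbct: Optional[ScalarVolume] = None

    def __post_init__(self) -> None:
        if self.acquired != (self.cbct is not None):
            raise ValueError("CBCT present iff acquired")
        if self.acquired != (self.ground_truth_field is not None):
            raise ValueError("ground-truth field present iff acquired")


class PatientSim(NamedTuple):
    anatomy: Anatomy
    scenarios: List[FractionScenario]
    config: PhantomConfig
    seed: int


# --------------------------------------------------------------------------
# schedule


def cbct_schedule(config: PhantomConfig) -> List[bool]:
    """Acquired-CBCT flag per fraction (1-based fraction f -> flags[f-1])."""
    daily, step = config.schedule_daily, config.schedule_interval
    flags = []
    for f in range(1, config.n_fractions + 1):
        flags.append(f <= daily or (f - daily) % step == 0)
    return flags


# --------------------------------------------------------------------------
# reference anatomy


def _ellipsoid(grid_mm, center, semiaxes) -> np.ndarray:
    x, y, z = grid_mm
    a, b, c = semiaxes
    cx, cy, cz = center
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


def _organ_layout(config: PhantomConfig) -> dict:
    """World-mm placement of every organ, derived from the lattice extent."""
    extent = np.array(config.shape) * np.array(config.spacing)
    ex, ey, ez = extent
    cx = ex / 2.0
    pa, pb, pc = config.prostate_semiaxes_mm
    prostate_c = (cx, 0.57 * ey, 0.44 * ez)
    # rectum directly posterior, anterior wall tangent to the prostate capsule
    # (no gap: the boost edge sits right at the prostate/rectum interface)
    rectum_y = prostate_c[1] + pb + config.rectum_radius_mm
    layout = {
        "body_center": (cx, ey / 2.0),
        "body_semiaxes": (0.44 * ex, 0.42 * ey),
        "prostate_center": prostate_c,
        "rectum_center_xy": (cx, rectum_y),
        "bladder_center": (cx, prostate_c[1] - 0.07 * ey, prostate_c[2] + pc + 0.75 * config.bladder_radius_mm),
        "vesicle_centers": [
            (cx - 10.0, prostate_c[1] + 8.0, prostate_c[2] + pc + 10.0),
            (cx + 10.0, prostate_c[1] + 8.0, prostate_c[2] + pc + 10.0),
        ],
        "vesicle_semiaxes": (9.0, 8.0, 14.0),
        "femoral_centers": [
            (cx - 0.35 * ex, ey / 2.0, 0.55 * ez),
            (cx + 0.35 * ex, ey / 2.0, 0.55 * ez),
        ],
        "femoral_radius": 16.0,
        "bulb_center": (cx, prostate_c[1] + 10.0, prostate_c[2] - pc - 9.0),
        "bulb_radius": 8.0,
    }
    # DIL center: offset along AP inside the prostate
    sign = 1.0 if config.dil_sector == "PZpm" else -1.0
    layout["dil_center"] = (
        cx,
        prostate_c[1] + sign * config.dil_offset_fraction * pb,
        prostate_c[2],
    )
    return layout


def build_reference_anatomy(config: PhantomConfig) -> Anatomy:
    """Create the reference HU volume and structure set for one patient."""
    spacing = np.asarray(config.spacing, dtype=np.float64)
    grids = np.ogrid[0 : config.shape[0], 0 : config.shape[1], 0 : config.shape[2]]
    grid_mm = [g.astype(np.float64) * s for g, s in zip(grids, spacing)]
    x, y, z = grid_mm
    lay = _organ_layout(config)

    bcx, bcy = lay["body_center"]
    bax, bay = lay["body_semiaxes"]
    body = ((x - bcx) / bax) ** 2 + ((y - bcy) / bay) ** 2 <= 1.0
    body = np.broadcast_to(body, config.shape).copy()

    prostate = _ellipsoid(grid_mm, lay["prostate_center"], config.prostate_semiaxes_mm)
    rcx, rcy = lay["rectum_center_xy"]
    rectum = np.broadcast_to(
        (x - rcx) ** 2 + (y - rcy) ** 2 <= config.rectum_radius_mm**2, config.shape
    ).copy()
    # rectum is a finite tube spanning the central SI range
    ez = config.shape[2] * spacing[2]
    rectum &= (z >= 0.12 * ez) & (z <= 0.85 * ez)
    rectum_lumen = np.broadcast_to(
        (x - rcx) ** 2 + (y - rcy) ** 2 <= (0.68 * config.rectum_radius_mm) ** 2, config.shape
    ).copy()
    rectum_lumen &= rectum

    r_b = config.bladder_radius_mm
    bladder = _ellipsoid(grid_mm, lay["bladder_center"], (r_b, r_b, r_b))
    vesicles = np.zeros(config.shape, dtype=bool)
    for c in lay["vesicle_centers"]:
        vesicles |= _ellipsoid(grid_mm, c, lay["vesicle_semiaxes"])
    vesicles &= ~prostate
    vesicles &= ~rectum

    femoral_L = _ellipsoid(grid_mm, lay["femoral_centers"][0], (lay["femoral_radius"],) * 3)
    femoral_R = _ellipsoid(grid_mm, lay["femoral_centers"][1], (lay["femoral_radius"],) * 3)
    bulb = _ellipsoid(grid_mm, lay["bulb_center"], (lay["bulb_radius"],) * 3)

    r_d = config.dil_radius_mm
    dil = _ellipsoid(grid_mm, lay["dil_center"], (r_d, r_d, r_d))
    if not dil.any():
        raise GeometryError("DIL mask is empty on this lattice")
    if (dil & ~prostate).any():
        raise GeometryError(
            "configured DIL placement reaches outside the prostate "
            f"(offset fraction {config.dil_offset_fraction}, radius {r_d} mm)"
        )

    # paint HU, later organs override earlier ones
    hu = np.full(config.shape, AIR_HU, dtype=np.float32)
    hu[body] = HU_VALUES["body"]
    hu[bladder & body] = HU_VALUES["bladder"]
    hu[rectum & body] = HU_VALUES["body"]  # rectal wall
    hu[rectum_lumen & body] = HU_VALUES["rectum_lumen"]
    hu[vesicles & body] = HU_VALUES["seminal_vesicles"]
    hu[prostate & body] = HU_VALUES["prostate"]
    hu[dil & body] = HU_VALUES["dil"]
    hu[femoral_L & body] = HU_VALUES["femoral_head"]
    hu[femoral_R & body] = HU_VALUES["femoral_head"]
    hu[bulb & body] = HU_VALUES["penile_bulb"]

    masks = {
        "body": body,
        "prostate": prostate & body,
        "seminal_vesicles": vesicles & body,
        "DIL": dil & body,
        "rectum": rectum & body,
        "bladder": bladder & body,
        "femoral_head_L": femoral_L & body,
        "femoral_head_R": femoral_R & body,
        "penile_bulb": bulb & body,
    }
    vol = ScalarVolume(hu, config.spacing)
    return Anatomy(vol, StructureSet(masks, config.spacing))


# --------------------------------------------------------------------------
# per-fraction motion + CBCT simulation


def _radial_component(grid_mm, center, scale, window_mm, out) -> None:
    """Accumulate scale * (x - c) * exp(-|x-c|^2 / (2 w^2)) into ``out``."""
    dx = [g - c for g, c in zip(grid_mm, center)]
    d2 = dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2
    w = np.exp(-d2 / (2.0 * window_mm**2)) * scale
    for ax in range(3):
        out[ax] += dx[ax] * w


def _ground_truth_field(
    anatomy: Anatomy,
    config: PhantomConfig,
    bladder_scale: float,
    rectum_scale: float,
    drift_mm: np.ndarray,
) -> np.ndarray:
    """Analytic reference-to-fraction displacement (3, nx, ny, nz) in mm."""
    shape = config.shape
    spacing = np.asarray(config.spacing)
    grids = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    grid_mm = [g.astype(np.float64) * s for g, s in zip(grids, spacing)]

    st = anatomy.structures
    u = [np.zeros(shape, dtype=np.float64) for _ in range(3)]
    if bladder_scale != 0.0:
        _radial_component(
            grid_mm, st.centroid_mm("bladder"), bladder_scale,
            2.0 * config.bladder_radius_mm, u,
        )
    if rectum_scale != 0.0:
        _radial_component(
            grid_mm, st.centroid_mm("rectum"), rectum_scale,
            2.0 * config.rectum_radius_mm, u,
        )
    if np.any(drift_mm != 0.0):
        c_p = st.centroid_mm("prostate")
        w_p = 1.8 * max(config.prostate_semiaxes_mm)
        d2 = sum((g - c) ** 2 for g, c in zip(grid_mm, c_p))
        win = np.exp(-d2 / (2.0 * w_p**2))
        for ax in range(3):
            u[ax] += drift_mm[ax] * win

    body = st["body"]
    field = np.stack([comp.astype(np.float32) for comp in u])
    field *= body[None]
    return field


def _invert_displacement(u: np.ndarray, spacing, n_iter: int = 6) -> np.ndarray:
    """Fixed-point inverse: find w with w(y) = -u(y + w(y))."""
    spacing = np.asarray(spacing, dtype=np.float32)
    w = np.zeros_like(u)
    base = voxel_index_grid(u.shape[1:])
    for _ in range(n_iter):
        coords = base + w / spacing[:, None, None, None]
        u_at = np.stack(
            [sample_at_voxel_coords(u[ax], coords, fill=0.0) for ax in range(3)]
        )
        w = -u_at
    return w


def _bias_field(shape, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean unit-SD field from upsampled low-resolution noise."""
    coarse = rng.standard_normal((6, 6, 5))
    zoom = [s / c for s, c in zip(shape, coarse.shape)]
    f = ndi.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
    f = f[: shape[0], : shape[1], : shape[2]]
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def simulate_fraction(
    anatomy: Anatomy,
    config: PhantomConfig,
    fraction_index: int,
    rng: np.random.Generator,
) -> FractionScenario:
    """Draw one fraction's motion, setup error and (if scheduled) CBCT.

    The same number of random variates is consumed whether or not the
    fraction is imaged, so the cohort is reproducible fraction-by-fraction.
    """
    if not 1 <= fraction_index <= config.n_fractions:
        raise ValueError(f"fraction_index must be in 1..{config.n_fractions}")
    acquired = cbct_schedule(config)[fraction_index - 1]

    bladder_scale, rectum_scale = rng.normal(0.0, 1.0, 2) * config.fill_scale_sd
    drift = rng.normal(0.0, 1.0, 3) * config.prostate_drift_sd_mm
    # rectal inflation pushes the prostate anteriorly (and vice versa)
    drift[1] -= config.rectum_prostate_coupling * rectum_scale * config.rectum_radius_mm
    shift = rng.normal(0.0, 1.0, 3) * np.asarray(config.couch_shift_sd_mm)
    noise_seed = int(rng.integers(0, 2**31 - 1))

    if not acquired:
        return FractionScenario(fraction_index, False, shift)

    u = _ground_truth_field(anatomy, config, bladder_scale, rectum_scale, drift)
    field = DeformationField(np.moveaxis(u, 0, -1), config.spacing)

    degraded = (
        np.any(u != 0.0)
        or np.any(shift != 0.0)
        or config.cbct_noise_sd_hu > 0
        or config.bias_amplitude_hu > 0
    )
    ref = anatomy.hu.data
    if not degraded:
        cbct_data = ref.copy()
    else:
        spacing = np.asarray(config.spacing, dtype=np.float32)
        # patient displaced by the setup error: CBCT(x) = anat_frac(x - shift)
        base = voxel_index_grid(ref.shape)
        coords = base - np.asarray(shift, dtype=np.float32)[:, None, None, None] / spacing[:, None, None, None]
        if np.any(u != 0.0):
            w = _invert_displacement(u, spacing)
            w_at = np.stack(
                [sample_at_voxel_coords(w[ax], coords, fill=0.0) for ax in range(3)]
            )
            coords = coords + w_at / spacing[:, None, None, None]
        cbct_data = sample_at_voxel_coords(ref, coords, fill=AIR_HU)

        noise_rng = np.random.default_rng(noise_seed)
        if config.bias_amplitude_hu > 0:
            bias = _bias_field(ref.shape, noise_rng)
            cbct_data = (cbct_data + 1000.0) * (
                1.0 + config.bias_amplitude_hu / 1000.0 * bias
            ) - 1000.0
        if config.cbct_noise_sd_hu > 0:
            cbct_data = cbct_data + noise_rng.normal(
                0.0, config.cbct_noise_sd_hu, ref.shape
            )
        cbct_data = cbct_data.astype(np.float32)

    cbct = ScalarVolume(cbct_data, config.spacing)
    return FractionScenario(fraction_index, True, shift, field, cbct)


# --------------------------------------------------------------------------
# cohort


def default_sector_assignment(n_patients: int, dorsal_fraction: float = 8.0 / 23.0) -> List[str]:
    """Deterministic dorsal/ventral split mirroring the ~35% dorsal prevalence."""
    n_dorsal = int(round(dorsal_fraction * n_patients))
    return ["PZpm"] * n_dorsal + ["ventral"] * (n_patients - n_dorsal)


def _jitter_config(config: PhantomConfig, rng: np.random.Generator) -> PhantomConfig:
    """Per-patient anatomical variability (mild size jitter, clipped)."""
    def j(v, rel=0.06, lo=0.85, hi=1.15):
        return float(v * np.clip(1.0 + rel * rng.standard_normal(), lo, hi))

    semi = tuple(j(s) for s in config.prostate_semiaxes_mm)
    # keep the lesion inside the (jittered) prostate at the configured offset
    dil_max = (1.0 - config.dil_offset_fraction) * semi[1] - 0.6
    dil = min(j(config.dil_radius_mm, rel=0.10, lo=0.8, hi=1.25), dil_max)
    return replace(
        config,
        prostate_semiaxes_mm=semi,
        bladder_radius_mm=j(config.bladder_radius_mm),
        rectum_radius_mm=j(config.rectum_radius_mm),
        dil_radius_mm=max(dil, 2.5),
    )


def generate_cohort(
    n_patients: int,
    config: PhantomConfig | None = None,
    seed: int = 0,
    sectors: Optional[Sequence[str]] = None,
    anatomical_jitter: bool = True,
) -> List[PatientSim]:
    """Simulate ``n_patients`` independent patients with 33 fractions each.

    Patient-level seeds are ``seed + patient_index``, so any patient can be
    regenerated in isolation.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if config is None:
        config = PhantomConfig()
    if sectors is None:
        sectors = default_sector_assignment(n_patients)
    if len(sectors) != n_patients:
        raise ValueError("sectors must have one entry per patient")

    cohort: List[PatientSim] = []
    for i in range(n_patients):
        p_seed = seed + i
        rng = np.random.default_rng(p_seed)
        p_config = replace(config, seed=p_seed, dil_sector=sectors[i])
        if anatomical_jitter:
            p_config = _jitter_config(p_config, rng)
        anatomy = build_reference_anatomy(p_config)
        scenarios = [
            simulate_fraction(anatomy, p_config, f, rng)
            for f in range(1, p_config.n_fractions + 1)
        ]
        cohort.append(PatientSim(anatomy, scenarios, p_config, p_seed))
    return cohort
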