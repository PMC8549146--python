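"""Rigid couch-shift alignment and deformable registration.

The deformable step is an intensity-driven, diffusion-regularized demons
registration run on density-overridden volumes.  Because those volumes are
piecewise constant, the image forces are concentrated at organ boundaries;
the regularization then propagates the boundary displacements into the
homogeneous interior.  The returned field follows the package-wide
reference-to-fraction convention, so dose pull-back needs no inversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .core import (
    DeformationField,
    ScalarVolume,
    sample_at_voxel_coords,
    voxel_index_grid,
)


@dataclass
class CouchShift:
    """Recorded 3-DOF translational setup correction (mm, LR/AP/SI), no rotation."""

    translation_mm: np.ndarray

    def __post_init__(self) -> None:
        self.translation_mm = np.asarray(self.translation_mm, dtype=np.float64).reshape(3)
        if not np.isfinite(self.translation_mm).all():
            raise ValueError("couch shift must be finite")


@dataclass
class RegistrationParams:
    """Demons knobs: multi-resolution schedule, smoothing, stopping rule.

    ``iterations_per_level`` may be a single int or one value per level
    (coarse to fine); the fine level dominates run time and mostly refines
    what the coarse levels already found, so the default spends fewer
    sweeps there.
    """

    levels: int = 3  # downsampling factors 2**(levels-1) ... 1
    iterations_per_level: Tuple[int, ...] | int = (50, 50, 25)
    sigma_fluid_mm: float = 2.0  # smoothing of each force increment
    sigma_diffusion_mm: float = 2.0  # smoothing of the accumulated field
    tolerance_mm: float = 0.01  # stop when the mean update falls below this
    max_step_mm: Optional[float] = None  # default: one voxel
    air_density_threshold: float = 0.05  # support mask: density above ~air
    track_similarity: bool = False  # record full-res similarity after each level

    def __post_init__(self) -> None:
        if isinstance(self.iterations_per_level, int):
            self.iterations_per_level = (self.iterations_per_level,) * self.levels
        self.iterations_per_level = tuple(self.iterations_per_level)
        if len(self.iterations_per_level) != self.levels:
            raise ValueError("need one iteration count per level")
        if self.levels < 1 or min(self.iterations_per_level) < 1:
            raise ValueError("levels and iterations must be >= 1")
        if min(self.sigma_fluid_mm, self.sigma_diffusion_mm) < 0:
            raise ValueError("smoothing sigmas must be >= 0")


# --------------------------------------------------------------------------
# rigid


def apply_couch_shift(
    volume: ScalarVolume, shift: CouchShift | np.ndarray, fill: float = 0.0
) -> ScalarVolume:
    """Resample onto the reference lattice translated by the recorded shift.

    ``out(x) = in(x + shift)``: applying the recorded correction to a CBCT
    acquired with setup error ``shift`` brings it into the reference frame.
    """
    t = shift.translation_mm if isinstance(shift, CouchShift) else np.asarray(shift, dtype=np.float64)
    t = t.reshape(3)
    if not np.isfinite(t).all():
        raise ValueError("couch shift must be finite")
    if np.all(t == 0.0):
        return volume.copy()
    spacing = np.asarray(volume.spacing, dtype=np.float32)
    coords = voxel_index_grid(volume.shape)
    coords += t.astype(np.float32)[:, None, None, None] / spacing[:, None, None, None]
    return volume.like(sample_at_voxel_coords(volume.data, coords, fill=fill))


# --------------------------------------------------------------------------
# demons


def _downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return np.asarray(arr, dtype=np.float32)
    sm = ndi.gaussian_filter(np.asarray(arr, dtype=np.float32), sigma=factor / 2.0)
    return sm[::factor, ::factor, ::factor]


def _upsample_field(u: np.ndarray, target_shape: Tuple[int, int, int]) -> np.ndarray:
    zoom = [t / c for t, c in zip(target_shape, u.shape[1:])]
    return np.stack(
        [ndi.zoom(u[ax], zoom, order=1, mode="nearest", grid_mode=True) for ax in range(3)]
    ).astype(np.float32)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(np.float64).ravel() - a.mean()
    b = b.astype(np.float64).ravel() - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 1.0


def deformable_register(
    fixed: ScalarVolume,
    moving: ScalarVolume,
    params: Optional[RegistrationParams] = None,
) -> DeformationField:
    """Demons registration of ``moving`` onto ``fixed`` (both density volumes).

    Returns the displacement field ``u`` with ``moving(x + u(x)) ~ fixed(x)``,
    i.e. reference-to-fraction when ``fixed`` is CT_ref and ``moving`` the
    aligned CBCT.  Deterministic: no random initialization.
    """
    if params is None:
        params = RegistrationParams()
    if not fixed.same_lattice(moving):
        raise ValueError("fixed and moving volumes live on different lattices")

    spacing_full = np.asarray(fixed.spacing, dtype=np.float32)
    max_step = params.max_step_mm if params.max_step_mm is not None else float(spacing_full.min())
    factors = [2 ** (params.levels - 1 - l) for l in range(params.levels)]
    traces: List[dict] = []

    # similarity is scored where the images initially disagree: elsewhere the
    # warp is ~identity and resampling can only blur
    mismatch = np.abs(fixed.data - moving.data) > 0.1
    moving_fill = float(np.asarray(moving.data).min())

    def _msd_at_full_res(u_any: np.ndarray) -> float:
        if not mismatch.any():
            return 0.0
        u_full = u_any if u_any.shape[1:] == fixed.shape else _upsample_field(u_any, fixed.shape)
        coords = voxel_index_grid(fixed.shape) + u_full / spacing_full[:, None, None, None]
        warped_now = sample_at_voxel_coords(moving.data, coords, fill=moving_fill)
        resid = (warped_now - fixed.data)[mismatch]
        return float(np.mean(resid.astype(np.float64) ** 2))

    similarity_trace: List[float] = []
    if params.track_similarity:
        similarity_trace.append(_msd_at_full_res(np.zeros((3,) + fixed.shape, dtype=np.float32)))

    u: Optional[np.ndarray] = None  # (3, nx, ny, nz) mm at current level
    for factor, n_iter in zip(factors, params.iterations_per_level):
        f = _downsample(fixed.data, factor)
        m = _downsample(moving.data, factor)
        sp = spacing_full * factor
        if u is None:
            u = np.zeros((3,) + f.shape, dtype=np.float32)
        else:
            u = _upsample_field(u, f.shape)

        grads = np.gradient(f.astype(np.float64), *sp)
        grads = [g.astype(np.float32) for g in grads]
        gnorm2 = grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2
        active = gnorm2 > 1e-12
        n_active = max(int(active.sum()), 1)
        base = voxel_index_grid(f.shape)
        sig_fluid_vox = params.sigma_fluid_mm / sp
        sig_diff_vox = params.sigma_diffusion_mm / sp
        level_trace = {"factor": factor, "mean_update_mm": []}

        for _ in range(n_iter):
            coords = base + u / sp[:, None, None, None]
            mw = sample_at_voxel_coords(m, coords, fill=float(m.min()))
            diff = mw - f
            denom = gnorm2 + diff * diff
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(denom > 1e-12, -diff / denom, 0.0).astype(np.float32)
            upd = np.stack([scale * g for g in grads])
            mag = np.sqrt((upd**2).sum(axis=0))
            over = mag > max_step
            if over.any():
                upd[:, over] *= (max_step / mag[over])[None]
            mean_update = float(mag.sum() / n_active)
            if params.sigma_fluid_mm > 0:
                for ax in range(3):
                    upd[ax] = ndi.gaussian_filter(upd[ax], sigma=sig_fluid_vox, truncate=2.0)
            u = u + upd
            if params.sigma_diffusion_mm > 0:
                for ax in range(3):
                    u[ax] = ndi.gaussian_filter(u[ax], sigma=sig_diff_vox, truncate=2.0)
            level_trace["mean_update_mm"].append(mean_update)
            if mean_update < params.tolerance_mm:
                break
        traces.append(level_trace)
        if params.track_similarity:
            similarity_trace.append(_msd_at_full_res(u))

    assert u is not None
    # the field is meaningless in surrounding air: clamp it to zero there
    support = (fixed.data > params.air_density_threshold) | (
        moving.data > params.air_density_threshold
    )
    support = ndi.binary_dilation(support, iterations=2)
    u[:, ~support] = 0.0

    ncc_initial = _ncc(fixed.data, moving.data)
    warped = sample_at_voxel_coords(
        moving.data,
        voxel_index_grid(fixed.shape) + u / spacing_full[:, None, None, None],
        fill=moving_fill,
    )
    ncc_final = _ncc(fixed.data, warped)
    meta = {
        "ncc_initial": ncc_initial,
        "ncc_final": ncc_final,
        "msd_mismatch_initial": _msd_at_full_res(np.zeros_like(u)) if mismatch.any() else 0.0,
        "msd_mismatch_final": _msd_at_full_res(u),
        "levels": traces,
    }
    if params.track_similarity:
        meta["msd_mismatch_per_level"] = similarity_trace

    return DeformationField(np.moveaxis(u, 0, -1), fixed.spacing, fixed.origin, meta=meta)


# --------------------------------------------------------------------------
# validation instruments


def field_quality(
    dvf: DeformationField, truth: DeformationField, region: np.ndarray
) -> dict:
    """Displacement-error summary of ``dvf`` against a ground-truth field."""
    if dvf.shape != truth.shape:
        raise ValueError("fields live on different lattices")
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty evaluation region")
    err = np.sqrt(((dvf.disp.astype(np.float64) - truth.disp.astype(np.float64)) ** 2).sum(axis=-1))
    vals = err[region]
    return {
        "mean_error_mm": float(vals.mean()),
        "p95_error_mm": float(np.percentile(vals, 95)),
        "min_jacobian": float(dvf.jacobian_determinant().min()),
    }


def compose_fields(outer: DeformationField, inner: DeformationField) -> DeformationField:
    """Displacement of ``phi_outer o phi_inner``: x -> x + u_in(x) + u_out(x + u_in(x))."""
    if outer.shape != inner.shape:
        raise ValueError("fields live on different lattices")
    spacing = np.asarray(inner.spacing, dtype=np.float32)
    base = voxel_index_grid(inner.shape)
    coords = base + np.moveaxis(inner.disp, -1, 0).astype(np.float32) / spacing[:, None, None, None]
    out_at = np.stack(
        [sample_at_voxel_coords(outer.disp[..., ax], coords, fill=0.0) for ax in range(3)]
    )
    total = np.moveaxis(out_at, 0, -1) + inner.disp
    return DeformationField(total, inner.spacing, inner.origin)
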