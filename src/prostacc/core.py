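"""Lattice-aligned volumetric containers shared by the whole pipeline.

Coordinate convention (used everywhere in this package):

* voxel indices are 0-based and ordered ``(LR, AP, SI)``:
  axis 0 runs left -> right, axis 1 anterior -> posterior,
  axis 2 inferior -> superior;
* world position of the *center* of voxel ``(i, j, k)`` is
  ``origin + index * spacing`` (mm);
* displacement vectors are expressed in mm in the same axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

AXIS_NAMES: Tuple[str, str, str] = ("LR", "AP", "SI")

Triple = Tuple[float, float, float]


def _as_triple(x) -> Triple:
    arr = tuple(float(v) for v in np.atleast_1d(x))
    if len(arr) == 1:
        arr = arr * 3
    if len(arr) != 3:
        raise ValueError(f"expected 3 components, got {x!r}")
    return arr  # type: ignore[return-value]


def _check_lattice(spacing: Triple) -> None:
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")


@dataclass
class ScalarVolume:
    """A 3-D lattice of scalars (HU, g/cm^3 or Gy) with geometric metadata."""

    data: np.ndarray
    spacing: Triple = (2.0, 2.0, 2.0)
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ScalarVolume.data must be 3-D")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        _check_lattice(self.spacing)
        if not np.isfinite(self.data).all():
            raise ValueError("ScalarVolume contains non-finite samples")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_lattice(self, other: "ScalarVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), self.spacing, self.origin)

    def like(self, data: np.ndarray) -> "ScalarVolume":
        """A new volume on this lattice carrying ``data``."""
        return ScalarVolume(data, self.spacing, self.origin)

    # ------------------------------------------------------------------ I/O
    def _affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self._affine())
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "ScalarVolume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(aff[i, i]) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return cls(np.asarray(img.get_fdata(), dtype=np.float32), spacing, origin)


@dataclass
class StructureSet:
    """Named binary masks sharing one lattice (targets, OARs, body)."""

    masks: Dict[str, np.ndarray]
    spacing: Triple = (2.0, 2.0, 2.0)
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        _check_lattice(self.spacing)
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks live on different lattices: {shapes}")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    @property
    def names(self):
        return list(self.masks)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return next(iter(self.masks.values())).shape  # type: ignore[return-value]

    def add(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask, dtype=bool)
        if self.masks and mask.shape != self.shape:
            raise ValueError("mask shape does not match structure-set lattice")
        self.masks[name] = mask

    def copy(self) -> "StructureSet":
        return StructureSet({k: v.copy() for k, v in self.masks.items()}, self.spacing, self.origin)

    def volume_cm3(self, name: str) -> float:
        voxel_mm3 = float(np.prod(self.spacing))
        return float(self.masks[name].sum()) * voxel_mm3 / 1000.0

    def centroid_mm(self, name: str) -> np.ndarray:
        idx = np.argwhere(self.masks[name])
        if idx.size == 0:
            raise ValueError(f"structure {name!r} is empty")
        return idx.mean(axis=0) * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass
class DeformationField:
    """Per-voxel displacement u(x) in mm on the reference lattice.

    Direction convention: a reference-frame point ``x`` corresponds to the
    fraction-frame point ``x + u(x)``, so dose defined on the fraction frame
    is pulled back by sampling it at ``x + u(x)``.
    """

    disp: np.ndarray  # (nx, ny, nz, 3), mm
    spacing: Triple = (2.0, 2.0, 2.0)
    origin: Triple = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise ValueError("DeformationField.disp must have shape (nx, ny, nz, 3)")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        _check_lattice(self.spacing)
        if not np.isfinite(self.disp).all():
            raise ValueError("DeformationField contains non-finite displacements")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.disp.shape[:3]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.disp.astype(np.float64) ** 2).sum(axis=-1))

    def jacobian_determinant(self) -> np.ndarray:
        """det(I + du/dx) per voxel; > 0 means locally invertible (no folding)."""
        u = self.disp.astype(np.float64)
        J = np.empty(self.shape + (3, 3))
        for i in range(3):
            grads = np.gradient(u[..., i], *self.spacing)
            for j in range(3):
                J[..., i, j] = grads[j]
            J[..., i, i] += 1.0
        return np.linalg.det(J)

    def to_nifti(self, path) -> None:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        img = nib.Nifti1Image(np.asarray(self.disp, dtype=np.float32), aff)
        img.header["descrip"] = b"displacement mm, reference-to-fraction"
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "DeformationField":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(aff[i, i]) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return cls(np.asarray(img.get_fdata(), dtype=np.float32), spacing, origin)


# --------------------------------------------------------------------------
# Sampling helpers


def voxel_index_grid(shape, dtype=np.float32) -> np.ndarray:
    """Stacked voxel index coordinates, shape (3, nx, ny, nz)."""
    return np.indices(shape, dtype=dtype)


def sample_at_voxel_coords(data: np.ndarray, coords: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Trilinear sampling of ``data`` at fractional voxel coordinates.

    ``coords`` has shape (3, ...); samples outside the lattice get ``fill``.
    """
    return ndi.map_coordinates(
        np.asarray(data, dtype=np.float32), coords, order=1, mode="constant", cval=fill
    )


def warp_volume_data(
    data: np.ndarray, disp_mm: np.ndarray, spacing, fill: float = 0.0
) -> np.ndarray:
    """Pull back ``data`` through a displacement field: out(x) = data(x + u(x))."""
    spacing = np.asarray(_as_triple(spacing), dtype=np.float32)
    coords = voxel_index_grid(data.shape)
    for ax in range(3):
        coords[ax] += np.asarray(disp_mm[..., ax], dtype=np.float32) / spacing[ax]
    return sample_at_voxel_coords(data, coords, fill=fill)
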