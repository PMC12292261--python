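"""Core volumetric data model: NIfTI I/O, warping, and finite-difference operators.

All image data lives in :class:`Volume` objects — a 3D scalar grid plus the
voxel size and a RAS voxel-to-world affine.  Dense deformations live in
:class:`DisplacementField` objects storing one 3-vector per voxel, in *voxel
units*, with pull-back sampling: the warped image at voxel ``v`` samples the
source image at ``v + d(v)``.  Keeping a single unit convention matters
because displacement fields are combined by direct voxel-wise weighted sums
during symmetric model construction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeError(ValueError):
    """Raised for invalid volumetric inputs (shape mismatch, non-finite data, ...)."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar intensity grid with spatial metadata.

    Parameters
    ----------
    data
        3D float array of intensities, axis order (x, y, z).
    affine
        4x4 voxel-to-world transform (RAS convention).  Defaults to a
        1 mm isotropic identity affine.
    """

    data: np.ndarray
    affine: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(4, dtype=float)
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeError(
                f"expected 3D volume, got {self.data.ndim}D with shape {self.data.shape}"
            )
        n_bad = int(np.count_nonzero(~np.isfinite(self.data)))
        if n_bad:
            raise VolumeError(f"volume contains {n_bad} non-finite voxels")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm, from the affine column norms."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume with the same metadata and the given data grid."""
        return Volume(data, self.affine.copy())

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())


@dataclasses.dataclass
class DisplacementField:
    """Dense displacement field in voxel units, pull-back convention.

    ``vectors`` has shape (nx, ny, nz, 3); component ``c`` of ``vectors[v]``
    displaces along grid axis ``c``.  Warping a source image I by this field
    produces ``I(v + d(v))``.
    """

    vectors: np.ndarray
    affine: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(4, dtype=float)
    )

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise VolumeError(
                f"displacement field must have shape (nx, ny, nz, 3), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise VolumeError("displacement field contains non-finite components")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean norm of the displacement, in voxels."""
        return np.linalg.norm(self.vectors, axis=-1)

    @classmethod
    def zeros(cls, shape: tuple[int, int, int], affine: np.ndarray | None = None) -> "DisplacementField":
        aff = np.eye(4) if affine is None else affine
        return cls(np.zeros(shape + (3,), dtype=np.float64), aff)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_nifti(path: str | Path) -> Volume:
    """Load a 3D NIfTI volume.

    Header scl_slope/scl_inter scaling is applied (nibabel's ``get_fdata``);
    no other rescaling happens.  4D images are rejected — this library
    operates on single structural volumes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise VolumeError(
            f"expected 3D volume, got {data.ndim}D with shape {data.shape} from {path}"
        )
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad:
        raise VolumeError(f"{path}: {n_bad} non-finite voxels")
    return Volume(data, np.asarray(img.affine, dtype=np.float64))


def write_nifti(vol: Volume, path: str | Path, allow_negative: bool = True) -> Path:
    """Write a Volume as NIfTI-1, preserving data, affine, and voxel size."""
    if not allow_negative and float(vol.data.min()) < 0:
        raise VolumeError("volume has negative intensities and allow_negative=False")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))
    return path


def read_field(path: str | Path) -> DisplacementField:
    """Load a displacement field stored as 5D NIfTI (nx, ny, nz, 1, 3)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim == 5 and data.shape[3] == 1:
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise VolumeError(f"expected a vector field NIfTI, got shape {data.shape}")
    return DisplacementField(data, np.asarray(img.affine, dtype=np.float64))


def write_field(field: DisplacementField, path: str | Path) -> Path:
    """Write a displacement field as 5D NIfTI with a singleton time axis."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = field.vectors[:, :, :, np.newaxis, :]
    img = nib.Nifti1Image(data, field.affine)
    img.header.set_data_dtype(np.float64)
    img.header.set_intent("vector")
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Warping and differential operators

_INTERP_ORDER = {"linear": 1, "spline": 3}


def warp(vol: Volume, d: DisplacementField, interp: str = "linear") -> Volume:
    """Resample ``vol`` through a displacement field: output(v) = vol(v + d(v)).

    Out-of-grid samples evaluate to 0 (skull-stripped background), and
    negative interpolated values are clamped to 0, so warps of nonnegative
    images stay nonnegative.
    """
    if interp not in _INTERP_ORDER:
        raise ValueError(f"interp must be one of {sorted(_INTERP_ORDER)}, got {interp!r}")
    if vol.shape != d.shape:
        raise VolumeError(f"shape mismatch: volume {vol.shape} vs field {d.shape}")
    if not d.vectors.any():  # exact identity for the zero field
        return vol.like(vol.data.copy())
    coords = _identity_coords(vol.shape) + np.moveaxis(d.vectors, -1, 0)
    out = ndimage.map_coordinates(
        vol.data, coords, order=_INTERP_ORDER[interp], mode="constant", cval=0.0
    )
    np.maximum(out, 0.0, out=out)
    return vol.like(out)


def _identity_coords(shape: tuple[int, int, int]) -> np.ndarray:
    return np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(np.float64)


def compose_fields(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Composition so that warping by the result equals warping by ``outer``
    then sampling through ``inner``:  d(v) = inner(v) + outer(v + inner(v)).

    ``warp(img, compose_fields(outer, inner)) ≈ warp(warp(img, outer), inner)``.
    """
    if outer.shape != inner.shape:
        raise VolumeError("cannot compose fields of different shapes")
    coords = _identity_coords(inner.shape) + np.moveaxis(inner.vectors, -1, 0)
    sampled = np.empty_like(outer.vectors)
    for c in range(3):
        sampled[..., c] = ndimage.map_coordinates(
            outer.vectors[..., c], coords, order=1, mode="nearest"
        )
    return DisplacementField(inner.vectors + sampled, inner.affine)


def gradient_magnitude(vol: Volume) -> Volume:
    """Per-voxel Euclidean norm of the intensity gradient, in voxel units.

    Central differences at interior voxels, one-sided at boundary faces, so
    every voxel of the grid carries a value.
    """
    gx, gy, gz = np.gradient(vol.data)
    return vol.like(np.sqrt(gx * gx + gy * gy + gz * gz))


def jacobian_determinant(d: DisplacementField) -> np.ndarray:
    """det(I + ∂d/∂v) per voxel, finite differences in voxel units.

    Positive everywhere for an orientation-preserving (diffeomorphic)
    deformation.
    """
    grads = [np.gradient(d.vectors[..., c]) for c in range(3)]  # grads[c][a] = ∂d_c/∂v_a
    J = np.empty(d.shape + (3, 3), dtype=np.float64)
    for c in range(3):
        for a in range(3):
            J[..., c, a] = grads[c][a]
        J[..., c, c] += 1.0
    return np.linalg.det(J)
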