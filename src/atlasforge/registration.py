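"""Registration backends behind a single contract.

``register(fixed, moving, backend)`` returns a pull-back displacement field
in voxel units such that ``warp(moving, d) ≈ fixed``.  The built-in backend
is multi-resolution Gaussian-regularized demons (SimpleITK's symmetric-forces
diffeomorphic demons), adequate for the smooth deformations of co-oriented
skull-stripped brains; SyN-class external engines can be adapted through the
same contract (any backend producing mm-space fields must convert to voxel
units on ingestion).
"""

from __future__ import annotations

import dataclasses
from typing import Protocol

import numpy as np
import SimpleITK as sitk

from .core import DisplacementField, Volume, VolumeError


class RegistrationBackend(Protocol):
    """Contract every registration engine must satisfy."""

    name: str

    def register(self, fixed: Volume, moving: Volume, mode: str = "deformable") -> DisplacementField:
        """Return a voxel-unit pull-back field with warp(moving, d) ≈ fixed."""
        ...


def _to_sitk(vol: Volume) -> sitk.Image:
    # SimpleITK arrays are indexed (z, y, x); our data is (x, y, z).
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.voxel_size))
    return img


def _field_from_sitk(disp: sitk.Image, vol: Volume) -> DisplacementField:
    arr = sitk.GetArrayFromImage(disp)  # (z, y, x, 3), physical units, (x, y, z) components
    vectors = np.ascontiguousarray(arr.transpose(2, 1, 0, 3))
    vectors /= np.asarray(vol.voxel_size)[None, None, None, :]
    return DisplacementField(vectors, vol.affine.copy())


@dataclasses.dataclass
class DemonsBackend:
    """Multi-resolution symmetric-forces diffeomorphic demons (SSD force).

    Parameters
    ----------
    iterations
        Per-level iteration counts, coarse to fine.
    shrink_factors
        Image pyramid shrink factors, matched to ``iterations``.
    smoothing_sigmas
        Gaussian pre-smoothing (physical units) per pyramid level.
    field_sigma
        Regularization of the total displacement field (physical units).
    update_sigma
        Regularization of the per-iteration update field; 0 disables it.
    """

    iterations: tuple[int, ...] = (40, 30, 20)
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (3.0, 1.5, 0.5)
    field_sigma: float = 1.2
    update_sigma: float = 0.0
    name: str = "demons"

    def register(self, fixed: Volume, moving: Volume, mode: str = "deformable") -> DisplacementField:
        if fixed.shape != moving.shape:
            raise VolumeError(
                f"fixed {fixed.shape} and moving {moving.shape} volumes must share a grid"
            )
        if mode == "affine":
            return _affine_register(fixed, moving)
        if mode != "deformable":
            raise ValueError(f"mode must be 'deformable' or 'affine', got {mode!r}")

        f_img = _to_sitk(fixed)
        m_img = _to_sitk(moving)
        filt = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        filt.SetSmoothDisplacementField(True)
        filt.SetStandardDeviations(self.field_sigma)
        if self.update_sigma > 0:
            filt.SetSmoothUpdateField(True)
            filt.SetUpdateFieldStandardDeviations(self.update_sigma)

        field: sitk.Image | None = None
        levels = zip(self.shrink_factors, self.smoothing_sigmas, self.iterations)
        for shrink, sigma, n_iter in levels:
            f_level = _shrink(f_img, shrink, sigma)
            m_level = _shrink(m_img, shrink, sigma)
            filt.SetNumberOfIterations(int(n_iter))
            if field is None:
                field = filt.Execute(f_level, m_level)
            else:
                field = sitk.Resample(field, f_level, sitk.Transform(), sitk.sitkLinear)
                field = sitk.Cast(field, sitk.sitkVectorFloat64)
                field = filt.Execute(f_level, m_level, field)
        assert field is not None
        field = sitk.Resample(field, f_img, sitk.Transform(), sitk.sitkLinear)
        return _field_from_sitk(sitk.Cast(field, sitk.sitkVectorFloat64), fixed)


def _shrink(img: sitk.Image, factor: int, sigma: float) -> sitk.Image:
    if sigma > 0:
        img = sitk.SmoothingRecursiveGaussian(img, sigma)
    if factor > 1:
        img = sitk.Shrink(img, [int(factor)] * 3)
    return img


def _affine_register(fixed: Volume, moving: Volume) -> DisplacementField:
    """12-DOF affine registration (mean-squares metric, full sampling),
    returned as a dense displacement field on the fixed grid."""
    f_img = sitk.Cast(_to_sitk(fixed), sitk.sitkFloat64)
    m_img = sitk.Cast(_to_sitk(moving), sitk.sitkFloat64)
    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.AffineTransform(3), sitk.CenteredTransformInitializerFilter.MOMENTS
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=100,
        relaxationFactor=0.5, gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetInitialTransform(initial, inPlace=False)
    transform = reg.Execute(f_img, m_img)
    disp = sitk.TransformToDisplacementField(
        transform, sitk.sitkVectorFloat64,
        f_img.GetSize(), f_img.GetOrigin(), f_img.GetSpacing(), f_img.GetDirection(),
    )
    return _field_from_sitk(disp, fixed)


def default_backend(**kwargs) -> DemonsBackend:
    return DemonsBackend(**kwargs)


def register(
    fixed: Volume,
    moving: Volume,
    backend: RegistrationBackend | None = None,
    mode: str = "deformable",
) -> DisplacementField:
    """Register ``moving`` onto ``fixed``; see module docstring for the contract."""
    if backend is None:
        backend = default_backend()
    return backend.register(fixed, moving, mode=mode)
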