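"""Synthetic skull-stripped brain phantoms with known ground truth.

The generator emulates what a preprocessed structural MRI cohort provides:
intensity-normalized brains on a common grid with zero background, differing
by smooth invertible deformations of one latent anatomy.  Population
asymmetry — clusters of near-duplicate subjects — is produced by letting
cluster members share a base deformation, which is exactly the
over-representation scenario the similarity-weighting stage is designed to
correct.  Every subject's true deformation from the latent template is
retained, enabling parameter-recovery tests with no data download.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import ndimage

from .core import DisplacementField, Volume, VolumeError, compose_fields, jacobian_determinant, warp

logger = logging.getLogger(__name__)

# Tissue intensities on the 0-100 normalized scale.
CSF_INTENSITY = 30.0
GM_INTENSITY = 60.0
WM_INTENSITY = 90.0
VENTRICLE_INTENSITY = 25.0


@dataclasses.dataclass
class PhantomSpec:
    """Configuration of a synthetic population.

    ``cluster_spec`` is a list of (cluster_size, intra_cluster_amplitude)
    pairs; members of one cluster share a base deformation of scale
    ``deformation_amplitude`` and differ only by perturbations of the listed
    intra-cluster amplitude (in voxels).  Cluster sizes must sum to
    ``n_subjects``.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    n_subjects: int = 7
    seed: int = 0
    deformation_amplitude: float = 4.0
    smoothness: float = 6.0
    cluster_spec: list[tuple[int, float]] | None = None
    noise_sd: float = 1.0
    outlier: tuple[int, float, float] | None = None  # (index, intensity shift, extra noise sd)
    bias_field: tuple[int, float] | None = None  # (polynomial order, relative amplitude)

    def resolved_clusters(self) -> list[tuple[int, float]]:
        if self.cluster_spec is None:
            return [(1, 0.0)] * self.n_subjects
        return list(self.cluster_spec)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("population needs n_subjects >= 2")
        sizes = [c[0] for c in self.resolved_clusters()]
        if any(s < 1 for s in sizes) or sum(sizes) != self.n_subjects:
            raise ValueError(
                f"cluster sizes {sizes} must be positive and sum to n_subjects={self.n_subjects}"
            )
        if self.deformation_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise_sd must be nonnegative")
        if self.outlier is not None and not 0 <= self.outlier[0] < self.n_subjects:
            raise ValueError("outlier index out of range")


@dataclasses.dataclass
class PhantomPopulation:
    """A generated cohort plus its ground truth."""

    subjects: list[Volume]
    true_fields: list[DisplacementField]
    latent_template: Volume
    wm_mask: Volume
    gm_mask: Volume
    outlier_index: int | None
    spec: PhantomSpec


def make_latent_template(
    shape: tuple[int, int, int] = (48, 48, 48),
    seed: int = 0,
    scale: float = 1.0,
) -> tuple[Volume, Volume, Volume]:
    """Build a nested-ellipsoid "brain" and its pure-tissue masks.

    Outer CSF-like shell, GM ring, WM core, and two ellipsoidal ventricles,
    with intensities in [0, 100] and exactly zero background.  The seed
    jitters the ellipsoid semi-axes (+/-8%) so different seeds give different
    anatomies; ``scale`` shrinks or grows the whole head, giving a family of
    deliberately shape-mismatched anatomies for usability experiments.

    Returns (template, wm_mask, gm_mask); masks mark pure-tissue voxels only
    (eroded one voxel away from class boundaries).
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 16 for s in shape):
        raise ValueError(f"each dimension must be >= 16, got {shape}")
    rng = np.random.default_rng(seed)
    jitter = 1.0 + 0.08 * rng.uniform(-1.0, 1.0, size=3)

    grid = np.stack(np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]], axis=-1).astype(float)
    center = (np.asarray(shape) - 1) / 2.0
    # Semi-axes as a fraction of the grid, slightly anisotropic like a brain.
    base = np.asarray(shape) * np.array([0.40, 0.44, 0.38]) * jitter * scale

    def ellipsoid_r(semi_axes: np.ndarray, offset: np.ndarray | None = None) -> np.ndarray:
        c = center if offset is None else center + offset
        return np.sqrt((((grid - c) / semi_axes) ** 2).sum(axis=-1))

    r_head = ellipsoid_r(base)
    data = np.zeros(shape, dtype=np.float64)
    data[r_head <= 1.0] = CSF_INTENSITY
    r_gm = ellipsoid_r(base * 0.88)
    data[r_gm <= 1.0] = GM_INTENSITY
    r_wm = ellipsoid_r(base * 0.68)
    data[r_wm <= 1.0] = WM_INTENSITY
    # Two lateral ventricles inside the WM core.
    vent_axes = base * np.array([0.12, 0.30, 0.14])
    for side in (-1.0, 1.0):
        offset = np.array([side * 0.18 * base[0], 0.0, 0.05 * base[2]])
        data[ellipsoid_r(vent_axes, offset) <= 1.0] = VENTRICLE_INTENSITY

    # Mild within-tissue texture so registration and radiomic features have
    # something to grip; kept small relative to class contrast.
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    texture *= 3.0 / max(texture.std(), 1e-12)
    data[data > 0] += texture[data > 0]
    data = np.clip(data, 0.0, 100.0)
    data[r_head > 1.0] = 0.0

    wm = ((r_wm <= 0.97) & (data > (GM_INTENSITY + WM_INTENSITY) / 2)).astype(np.float64)
    gm = ((r_gm <= 0.97) & (r_wm > 1.03) & (data > (CSF_INTENSITY + GM_INTENSITY) / 2)).astype(
        np.float64
    )
    vol = Volume(data)
    return vol, vol.like(wm), vol.like(gm)


def _smooth_velocity(
    shape: tuple[int, int, int], amplitude: float, smoothness: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-filtered white-noise velocity scaled to a max-norm amplitude."""
    v = rng.standard_normal(shape + (3,))
    for c in range(3):
        v[..., c] = ndimage.gaussian_filter(v[..., c], smoothness)
    peak = float(np.linalg.norm(v, axis=-1).max())
    if peak > 0 and amplitude > 0:
        v *= amplitude / peak
    else:
        v[:] = 0.0
    return v


def _exponentiate(v: np.ndarray, n_squarings: int = 6) -> DisplacementField:
    """Scaling-and-squaring exponential of a stationary velocity field."""
    d = DisplacementField(v / (2.0**n_squarings))
    for _ in range(n_squarings):
        d = compose_fields(d, d)
    return d


def random_diffeomorphism(
    shape: tuple[int, int, int],
    amplitude: float = 2.0,
    smoothness: float = 6.0,
    seed: int = 0,
    n_squarings: int = 6,
) -> DisplacementField:
    """Draw a smooth invertible displacement field.

    A Gaussian-filtered white-noise stationary velocity field, scaled so its
    largest vector has the requested amplitude (voxels), is integrated by
    scaling and squaring.  Invertibility is verified via min det(I + ∇d) > 0
    on interior voxels; on failure the amplitude is halved (with a warning)
    until the check passes.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    rng = np.random.default_rng(seed)
    v = _smooth_velocity(shape, amplitude, smoothness, rng)
    while True:
        d = _exponentiate(v, n_squarings)
        if amplitude == 0 or _min_interior_jacobian(d) > 0:
            return d
        warnings.warn(
            "generated field failed the invertibility check; halving amplitude",
            stacklevel=2,
        )
        v *= 0.5
        amplitude *= 0.5


def velocity_to_inverse_field(v: np.ndarray, n_squarings: int = 6) -> DisplacementField:
    """Exponential of the negated velocity — the exact-group inverse of
    :func:`random_diffeomorphism`'s output for the same velocity."""
    return _exponentiate(-v, n_squarings)


def _min_interior_jacobian(d: DisplacementField) -> float:
    detj = jacobian_determinant(d)
    return float(detj[1:-1, 1:-1, 1:-1].min())


def _polynomial_bias(shape: tuple[int, int, int], order: int, amplitude: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias field 1 + amplitude * p(x) with random
    low-order polynomial p normalized to [-1, 1]."""
    coords = [np.linspace(-1.0, 1.0, s) for s in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    field = np.zeros(shape)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if i + j + k == 0:
                    continue
                field += rng.normal() * (X**i) * (Y**j) * (Z**k)
    peak = float(np.abs(field).max())
    if peak > 0:
        field /= peak
    return 1.0 + amplitude * field


def make_population(spec: PhantomSpec) -> PhantomPopulation:
    """Generate a deterministic synthetic cohort from a :class:`PhantomSpec`.

    Subjects within one cluster share a base velocity field; each subject
    adds its own small perturbation velocity, and the summed velocity is
    exponentiated so every true deformation is an exact diffeomorphism.
    Noise is additive Gaussian clamped at zero (the cohort emulates denoised,
    skull-stripped data).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    latent, wm, gm = make_latent_template(spec.shape, seed=int(rng.integers(2**31)))

    subjects: list[Volume] = []
    true_fields: list[DisplacementField] = []
    idx = 0
    for size, intra_amp in spec.resolved_clusters():
        v_base = _smooth_velocity(
            spec.shape, spec.deformation_amplitude, spec.smoothness,
            np.random.default_rng(int(rng.integers(2**31))),
        )
        for _ in range(size):
            v_pert = _smooth_velocity(
                spec.shape, intra_amp, spec.smoothness,
                np.random.default_rng(int(rng.integers(2**31))),
            )
            d = _exponentiate(v_base + v_pert)
            if _min_interior_jacobian(d) <= 0 and spec.deformation_amplitude > 0:
                logger.warning("subject %d field non-invertible; halving velocity", idx)
                d = _exponentiate(0.5 * (v_base + v_pert))
            img = warp(latent, d, interp="linear")
            data = img.data
            if spec.bias_field is not None:
                order, amp = spec.bias_field
                bias_rng = np.random.default_rng(int(rng.integers(2**31)))
                data = data * _polynomial_bias(spec.shape, order, amp, bias_rng)
            noise_rng = np.random.default_rng(int(rng.integers(2**31)))
            if spec.noise_sd > 0:
                # Foreground-only noise: skull-stripped, denoised data keeps
                # an exactly-zero background.
                fg = data > 0
                data[fg] += noise_rng.normal(0.0, spec.noise_sd, int(fg.sum()))
            subjects.append(latent.like(np.clip(data, 0.0, None)))
            true_fields.append(d)
            idx += 1

    outlier_index = None
    if spec.outlier is not None:
        outlier_index, shift, extra_sd = spec.outlier
        out_rng = np.random.default_rng(int(rng.integers(2**31)))
        data = subjects[outlier_index].data.copy()
        fg = data > 0
        data[fg] += shift
        if extra_sd > 0:
            data[fg] += out_rng.normal(0.0, extra_sd, int(fg.sum()))
        subjects[outlier_index] = latent.like(np.clip(data, 0.0, None))

    return PhantomPopulation(
        subjects=subjects,
        true_fields=true_fields,
        latent_template=latent,
        wm_mask=wm,
        gm_mask=gm,
        outlier_index=outlier_index,
        spec=spec,
    )


def asymmetric_spec(seed: int, shape: tuple[int, int, int] = (48, 48, 48)) -> PhantomSpec:
    """The canonical asymmetric study population: one 4-subject
    near-duplicate cluster among N=7, plus an intensity-shifted outlier
    (one of the singleton subjects)."""
    return PhantomSpec(
        shape=shape,
        n_subjects=7,
        seed=seed,
        deformation_amplitude=4.0,
        smoothness=6.0,
        cluster_spec=[(4, 1.0), (1, 0.0), (1, 0.0), (1, 0.0)],
        noise_sd=1.0,
        outlier=(6, 15.0, 0.0),
    )


def symmetric_spec(seed: int, shape: tuple[int, int, int] = (48, 48, 48)) -> PhantomSpec:
    """A symmetric population: seven exchangeable subjects, no clusters, no
    outlier."""
    return PhantomSpec(
        shape=shape,
        n_subjects=7,
        seed=seed,
        deformation_amplitude=4.0,
        smoothness=6.0,
        cluster_spec=None,
        noise_sd=1.0,
        outlier=None,
    )


def misaligned_stack_spec(seed: int, shape: tuple[int, int, int] = (48, 48, 48)) -> PhantomSpec:
    """A residually misaligned aligned stack: what a population looks like
    *after* deformable alignment to a common center, with the ~1-voxel
    residual misalignment real registration leaves, plus an
    intensity-shifted outlier.  Used to compare intensity-fusion methods."""
    return PhantomSpec(
        shape=shape,
        n_subjects=7,
        seed=seed,
        deformation_amplitude=1.0,
        smoothness=5.0,
        cluster_spec=None,
        noise_sd=1.0,
        outlier=(6, 15.0, 0.0),
    )


def estimate_background_noise_sd(vol: Volume, background_mask: Volume) -> float:
    """Sample SD (ddof=1) of intensities inside a background mask."""
    mask = background_mask.data > 0
    n = int(mask.sum())
    if n == 0:
        raise VolumeError("background mask is empty")
    if n == 1:
        return 0.0
    return float(np.std(vol.data[mask], ddof=1))
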