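"""Weighted symmetric model construction (SMC).

SMC estimates a population's structural center without iterative averaging:
pick any reference subject, register it to every other subject, and warp it
by the weighted sum of those pairwise displacement fields

    dw_j = sum_{i != j} d_ji * NW_i

where NW are the per-subject similarity weights (the reference's own weight
multiplies its implicit zero self-displacement, so uniform NW = 1/N recovers
the unweighted SMC mean).  Deweighting over-represented subjects keeps the
center from drifting toward a cluster of near-duplicates.  All remaining
subjects are then registered to the center, producing the aligned stack the
intensity-fusion stage consumes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._parallel import parallel_map
from .core import DisplacementField, Volume, VolumeError, warp
from .registration import RegistrationBackend, default_backend, register
from .weights import SimilarityWeights


@dataclasses.dataclass
class CenterResult:
    """Everything the weighted-SMC stage produces."""

    center: Volume
    weighted_displacement_field: DisplacementField
    pairwise_fields: list[DisplacementField | None]  # entry j (reference) is None
    reference_index: int
    aligned: list[Volume] | None = None
    alignment_fields: list[DisplacementField] | None = None


def weighted_displacement_sum(
    pairwise_fields: list[DisplacementField | None],
    NW: np.ndarray,
    reference_index: int,
) -> DisplacementField:
    """dw_j = sum_{i != j} d_ji * NW_i, elementwise over the voxel grid.

    Weights are taken as given (no renormalization over the i != j subset).
    """
    shapes = {f.shape for f in pairwise_fields if f is not None}
    if len(shapes) != 1:
        raise VolumeError("pairwise fields must share one grid")
    template_field = next(f for f in pairwise_fields if f is not None)
    total = np.zeros_like(template_field.vectors)
    for i, field in enumerate(pairwise_fields):
        if i == reference_index or field is None:
            continue
        total += field.vectors * float(NW[i])
    return DisplacementField(total, template_field.affine.copy())


def weighted_center(
    images: list[Volume],
    NW: SimilarityWeights | np.ndarray,
    reference_index: int = 0,
    backend: RegistrationBackend | None = None,
    n_workers: int = 1,
) -> CenterResult:
    """Estimate the similarity-weighted structural center of a population.

    The reference image is registered to each other subject (moving =
    reference, fixed = subject, i.e. warp(reference, d_ji) ≈ subject); the
    NW-weighted sum of those fields warps the reference to the center.
    Pairwise registrations are independent pure functions, so the result is
    identical for any worker count.
    """
    n = len(images)
    if n < 2:
        raise ValueError("need at least 2 images")
    weights = NW.normalized if isinstance(NW, SimilarityWeights) else np.asarray(NW, float)
    if len(weights) != n:
        raise ValueError(f"weight vector length {len(weights)} != population size {n}")
    if not 0 <= reference_index < n:
        raise ValueError("reference_index out of range")
    if backend is None:
        backend = default_backend()

    ref = images[reference_index]
    others = [i for i in range(n) if i != reference_index]
    fields = parallel_map(
        lambda i: register(images[i], ref, backend=backend), others, n_workers=n_workers
    )
    pairwise: list[DisplacementField | None] = [None] * n
    for i, f in zip(others, fields):
        pairwise[i] = f

    dw = weighted_displacement_sum(pairwise, weights, reference_index)
    center = warp(ref, dw, interp="linear")
    return CenterResult(
        center=center,
        weighted_displacement_field=dw,
        pairwise_fields=pairwise,
        reference_index=reference_index,
    )


def align_population(
    images: list[Volume],
    center: Volume,
    backend: RegistrationBackend | None = None,
    n_workers: int = 1,
) -> tuple[list[Volume], list[DisplacementField]]:
    """Deformably register every subject to the center.

    Returns the warped images I' (on the center's grid) and the displacement
    fields d_ic consumed by the weighted-displacement bias metric.
    """
    if backend is None:
        backend = default_backend()
    fields = parallel_map(
        lambda img: register(center, img, backend=backend), images, n_workers=n_workers
    )
    aligned = [warp(img, d, interp="linear") for img, d in zip(images, fields)]
    return aligned, fields
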