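"""Template evaluation metrics.

Five complementary measures:

* **WD** — similarity-weighted sum of squared displacement magnitudes from
  each subject to the center; lower = structurally less biased center.
* **AGM** — mean voxelwise gradient norm; higher = sharper template.
* **NMC** — normalized Michelson contrast (WM_max − GM_min)/(WM_max + GM_min)
  between pure white- and gray-matter voxels.
* **D_KL** — Kullback–Leibler divergence between template and subject
  intensity histograms; an outlier-robust template stays close to the
  population mode.
* **mLJD** — mean log |Jacobian determinant| of a deformation field;
  near 0 = little volume change needed to reach the template.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import DisplacementField, Volume, VolumeError, gradient_magnitude, jacobian_determinant
from .registration import RegistrationBackend, default_backend, register
from .weights import SimilarityWeights


@dataclasses.dataclass
class TissueMasks:
    wm: Volume
    gm: Volume

    def __post_init__(self) -> None:
        if np.any((self.wm.data > 0) & (self.gm.data > 0)):
            raise VolumeError("WM and GM masks overlap")


def weighted_displacement(
    fields: list[DisplacementField],
    NW: SimilarityWeights | np.ndarray,
) -> tuple[float, float]:
    """WD = sum_i ( sum_v ||d_ic(v)||² ) · NW_i.

    Returns (total, per-voxel average = total / M); units voxel².
    """
    weights = NW.normalized if isinstance(NW, SimilarityWeights) else np.asarray(NW, float)
    if len(fields) != len(weights):
        raise ValueError("one weight per field required")
    shapes = {f.shape for f in fields}
    if len(shapes) != 1:
        raise VolumeError("fields must share one grid")
    total = 0.0
    for field, w in zip(fields, weights):
        total += float((field.vectors**2).sum()) * float(w)
    m = int(np.prod(fields[0].shape))
    return total, total / m


def avg_gradient_magnitude(T: Volume, mask: Volume | None = None) -> float:
    """AGM = (1/M) sum_v ||∇T(v)||₂, by default over all M voxels.

    An optional mask restricts the domain (e.g. the brain foreground).  On
    small grids the whole-grid value is dominated by the background/boundary
    halo of averaged templates rather than by anatomical sharpness, so
    template comparisons should mask to the brain.
    """
    g = gradient_magnitude(T).data
    if mask is not None:
        m = mask.data > 0
        if not m.any():
            raise VolumeError("empty AGM mask")
        return float(g[m].mean())
    return float(g.mean())


def michelson_contrast(T: Volume, masks: TissueMasks) -> float:
    """NMC = (WM_max − GM_min) / (WM_max + GM_min) on pure-tissue voxels."""
    wm = masks.wm.data > 0
    gm = masks.gm.data > 0
    if not wm.any() or not gm.any():
        raise VolumeError("both tissue masks must be nonempty")
    wm_max = float(T.data[wm].max())
    gm_min = float(T.data[gm].min())
    denom = wm_max + gm_min
    if denom == 0:
        raise ZeroDivisionError("WM_max + GM_min = 0: contrast undefined")
    return (wm_max - gm_min) / denom


def kl_divergence_discrete(p: np.ndarray, q: np.ndarray) -> float:
    """D_KL(P‖Q) = sum_x P(x) ln(P(x)/Q(x)) in nats for given histograms;
    terms with P(x)=0 contribute 0."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("histograms must have equal length")
    p = p / p.sum()
    q = q / q.sum()
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("P(x)>0 where Q(x)=0: divergence infinite; smooth the histograms")
    return float((p[mask] * np.log(p[mask] / q[mask])).sum())


def kl_divergence(
    template: Volume,
    image: Volume,
    bins: int = 100,
    foreground_only: bool = True,
) -> float:
    """D_KL between the intensity distributions of template and image.

    Histograms share bin edges over the union intensity range; one Laplace
    pseudo-count per bin is added to both before normalizing, so empty bins
    never produce infinities.  By default only nonzero (foreground) voxels
    enter the histograms.
    """
    a = template.data[template.data > 0] if foreground_only else template.data.ravel()
    b = image.data[image.data > 0] if foreground_only else image.data.ravel()
    if a.size == 0 or b.size == 0:
        raise VolumeError("empty foreground")
    lo = min(float(a.min()), float(b.min()))
    hi = max(float(a.max()), float(b.max()))
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(a, bins=edges)
    q, _ = np.histogram(b, bins=edges)
    return kl_divergence_discrete((p + 1) / (p.sum() + bins), (q + 1) / (q.sum() + bins))


def mean_log_jacobian(d: DisplacementField, domain_mask: Volume | None = None) -> float:
    """mLJD = (1/M) sum_v ln |det(I + ∂d/∂v)| (voxel units, central
    differences).  Positive = net expansion, negative = net compression."""
    detj = jacobian_determinant(d)
    logdet = np.log(np.abs(detj) + np.finfo(float).tiny)
    if domain_mask is not None:
        mask = domain_mask.data > 0
        if not mask.any():
            raise VolumeError("empty domain mask")
        return float(logdet[mask].mean())
    return float(logdet.mean())


def compare_template_usability(
    subjects: list[Volume],
    templates: list[Volume],
    backend: RegistrationBackend | None = None,
    template_names: list[str] | None = None,
    affine_prealign: bool = False,
) -> dict[str, dict[str, object]]:
    """Deformation burden of registering subjects onto candidate templates.

    Each subject is (optionally affinely, then) deformably registered to
    each template; the mLJD of every deformation field is recorded and
    per-template medians reported.  The template matching the subjects'
    population should need the least volume change — |median mLJD| closest
    to zero.
    """
    if not subjects or len(templates) < 2:
        raise ValueError("need >= 1 subject and >= 2 templates")
    backend = backend or default_backend()
    names = template_names or [f"template_{i}" for i in range(len(templates))]
    out: dict[str, dict[str, object]] = {}
    for name, tpl in zip(names, templates):
        mljds = []
        for subj in subjects:
            moving = subj
            if affine_prealign:
                aff = register(tpl, subj, backend=backend, mode="affine")
                from .core import warp

                moving = warp(subj, aff, interp="linear")
            d = register(tpl, moving, backend=backend)
            mljds.append(mean_log_jacobian(d))
        out[name] = {"mljd": mljds, "median_mljd": float(np.median(mljds))}
    return out
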