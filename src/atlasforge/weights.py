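"""Per-subject similarity weights from an image feature matrix.

The weighting deweights near-duplicate subjects so the structural center is
not dragged toward over-represented anatomy.  Pipeline: z-score features
across subjects, PCA (keep the fewest components reaching the variance
target, capped), form an N x N subject similarity (kernel covariance)
matrix from the component-score vectors, take its Moore-Penrose
pseudo-inverse, and sum each subject's row; normalizing the row sums to one
yields weights where a large value marks a subject *distinct* from the rest
and duplicated subjects split the weight a unique subject would have
received.

"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats

from .core import Volume, VolumeError

logger = logging.getLogger(__name__)

N_BLOCKS = 4  # regional fingerprint resolution per axis

FEATURE_NAMES: tuple[str, ...] = (
    "mean", "sd", "skewness", "kurtosis",
    "p10", "p25", "p50", "p75", "p90",
    "entropy", "energy", "min", "max",
    "volume_voxels", "surface_to_volume", "extent_x", "extent_y", "extent_z",
    "paxis_1", "paxis_2", "paxis_3",
) + tuple(
    f"block_mean_{i}_{j}_{k}"
    for i in range(N_BLOCKS) for j in range(N_BLOCKS) for k in range(N_BLOCKS)
)


@dataclasses.dataclass
class FeatureMatrix:
    """N subjects x P features, with feature labels."""

    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2D (subjects x features)")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length mismatch")


@dataclasses.dataclass
class SimilarityWeights:
    """Raw pseudo-inverse row sums W and normalized weights NW (sum to 1)."""

    raw: np.ndarray
    normalized: np.ndarray
    n_components_kept: int
    explained_variance_ratio: float


def extract_features(vol: Volume, mask: Volume) -> np.ndarray:
    """First-order intensity statistics, shape descriptors, and a regional
    block-mean fingerprint on a masked region — a compact stand-in for a
    full radiomics catalogue, sufficient to measure inter-subject
    similarity.  Global histogram statistics are nearly invariant under
    smooth warps, so the 4x4x4 grid of masked block means carries the
    spatial-arrangement information that texture features would provide.
    Order follows :data:`FEATURE_NAMES`."""
    m = mask.data > 0
    n = int(m.sum())
    if n == 0:
        raise VolumeError("empty mask")
    vals = vol.data[m]

    sd = float(vals.std())
    if n > 2 and sd > 0:
        skew = float(stats.skew(vals))
        kurt = float(stats.kurtosis(vals))
    else:
        skew = kurt = 0.0
    # Shannon entropy of a fixed 64-bin histogram over the region's range.
    hist, _ = np.histogram(vals, bins=64)
    p = hist / n
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    energy = float((p**2).sum())

    idx = np.argwhere(m).astype(float)
    extents = idx.max(axis=0) - idx.min(axis=0) + 1.0
    centered = idx - idx.mean(axis=0)
    if n > 3:
        cov = np.cov(centered, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        paxes = 4.0 * np.sqrt(np.maximum(eigvals, 0.0))
    else:
        paxes = np.zeros(3)
    # Surface proxy: masked voxels with at least one 6-neighbor outside.
    surface = n - int(_eroded_count(m))

    feats = [
        float(vals.mean()), sd, skew, kurt,
        *(float(np.percentile(vals, q)) for q in (10, 25, 50, 75, 90)),
        entropy, energy, float(vals.min()), float(vals.max()),
        float(n), surface / n, *extents.tolist(), *paxes.tolist(),
        *_block_means(vol.data, m),
    ]
    return np.asarray(feats, dtype=float)


def _block_means(data: np.ndarray, mask: np.ndarray) -> list[float]:
    """Mean masked intensity in each cell of an N_BLOCKS^3 grid (0 where the
    cell holds no masked voxels)."""
    out = []
    bounds = [np.linspace(0, s, N_BLOCKS + 1).astype(int) for s in data.shape]
    for i in range(N_BLOCKS):
        for j in range(N_BLOCKS):
            for k in range(N_BLOCKS):
                sl = (slice(bounds[0][i], bounds[0][i + 1]),
                      slice(bounds[1][j], bounds[1][j + 1]),
                      slice(bounds[2][k], bounds[2][k + 1]))
                cell_mask = mask[sl]
                out.append(float(data[sl][cell_mask].mean()) if cell_mask.any() else 0.0)
    return out


def _eroded_count(mask: np.ndarray) -> int:
    core = mask.copy()
    for axis in range(3):
        for shift in (1, -1):
            core &= np.roll(mask, shift, axis=axis)
    # np.roll wraps; voxels on the grid boundary are treated as surface
    core[0, :, :] = core[-1, :, :] = False
    core[:, 0, :] = core[:, -1, :] = False
    core[:, :, 0] = core[:, :, -1] = False
    return int(core.sum())


def features_from_population(volumes: list[Volume], masks: list[Volume] | None = None) -> FeatureMatrix:
    """Stack per-subject feature vectors; default mask is each subject's
    nonzero foreground."""
    rows = []
    for i, vol in enumerate(volumes):
        mask = masks[i] if masks is not None else vol.like((vol.data > 0).astype(float))
        rows.append(extract_features(vol, mask))
    return FeatureMatrix(np.vstack(rows), list(FEATURE_NAMES))


def subject_similarity_matrix(scores: np.ndarray, ridge: float = 0.25) -> np.ndarray:
    """N x N similarity (kernel covariance) matrix of subject score vectors.

    Gaussian kernel of pairwise score distances with the median pairwise
    distance as bandwidth, plus a small ridge on the diagonal.  This keeps
    the matrix positive definite with unit-scale diagonal, so the
    pseudo-inverse row sums are well conditioned even when near-duplicate
    subjects make the similarity block singular.  A sample covariance of
    across-subject-centered scores is unusable here: the all-ones vector
    lies exactly in its null space, forcing every pseudo-inverse row sum to
    zero.
    """
    from scipy.spatial.distance import pdist, squareform

    n = scores.shape[0]
    dist = squareform(pdist(scores))
    upper = dist[np.triu_indices(n, 1)]
    h = float(np.median(upper))
    sigma = np.exp(-(dist**2) / (2.0 * h * h)) if h > 0 else np.ones((n, n))
    return sigma + ridge * np.eye(n)


def compute_similarity_weights(
    F: FeatureMatrix,
    variance_target: float = 0.95,
    max_components: int = 5,
    ridge: float = 0.25,
    clip_negative: bool = False,
) -> SimilarityWeights:
    """Similarity weights from a subjects-by-features matrix.

    Subjects that resemble many others sit in a high-similarity block of the
    subject matrix, and the block's inverse splits the block's total weight
    among its members; a subject unlike the rest keeps its full weight.
    Raises on degenerate inputs (all features constant, or raw weights
    summing to 0, where normalization would be meaningless).
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    X = F.values
    n = X.shape[0]

    sd = X.std(axis=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance features before PCA", n_dropped)
    if not keep.any():
        raise ValueError("all features have zero variance across subjects")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    # PCA across subjects on the z-scored features; keep the fewest
    # components reaching the variance target, capped.
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    total = (s**2).sum()
    if total <= 0:
        raise ValueError("feature matrix has no across-subject variation")
    cumvar = np.cumsum(s**2) / total
    k = int(np.searchsorted(cumvar, variance_target - 1e-12) + 1)
    rank = int((s > s[0] * max(Z.shape) * np.finfo(float).eps).sum())
    k = min(max(k, 1), max_components, max(rank, 1))
    scores = U[:, :k] * s[:k]

    sigma = subject_similarity_matrix(scores, ridge=ridge)
    sigma_pinv = np.linalg.pinv(sigma, hermitian=True)
    W = sigma_pinv.sum(axis=1)
    total = W.sum()
    if abs(total) < 1e-12:
        raise ValueError("degenerate normalization: raw weights sum to 0")
    NW = W / total
    if np.any(NW < 0):
        if clip_negative:
            logger.warning("negative weights clipped to 0 and renormalized")
            NW = np.clip(NW, 0.0, None)
            NW = NW / NW.sum()
        else:
            logger.warning("negative normalized weights present (not clipped)")
    return SimilarityWeights(
        raw=W,
        normalized=NW,
        n_components_kept=k,
        explained_variance_ratio=float(cumvar[k - 1]),
    )


def uniform_weights(n: int) -> SimilarityWeights:
    """The unweighted baseline: NW = 1/N, recovering plain symmetric model
    construction."""
    w = np.full(n, 1.0 / n)
    return SimilarityWeights(raw=w.copy(), normalized=w, n_components_kept=0,
                             explained_variance_ratio=0.0)
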