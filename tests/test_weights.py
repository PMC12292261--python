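"""Similarity weighting: features, normalization, deweighting, oracle."""

import numpy as np
import pytest

from atlasforge.core import Volume, VolumeError
from atlasforge.weights import (
    FEATURE_NAMES,
    FeatureMatrix,
    compute_similarity_weights,
    extract_features,
    features_from_population,
    uniform_weights,
)


def brute_force_weights(X, variance_target=0.95, max_components=5, ridge=0.25):
    """Independent re-derivation with explicit loops and an explicit SVD
    pseudo-inverse; mirrors the documented algorithm, shares no code with
    the implementation."""
    X = np.asarray(X, float)
    keep = [j for j in range(X.shape[1]) if X[:, j].std() > 0]
    Z = np.empty((X.shape[0], len(keep)))
    for c, j in enumerate(keep):
        col = X[:, j]
        Z[:, c] = (col - col.mean()) / col.std()
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    cum = np.cumsum(s**2) / (s**2).sum()
    k = 1
    while cum[k - 1] < 0.95 - 1e-12:
        k += 1
    rank = int((s > s[0] * max(Z.shape) * np.finfo(float).eps).sum())
    k = min(max(k, 1), max_components, max(rank, 1))
    S = U[:, :k] * s[:k]
    n = S.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = np.sqrt(((S[i] - S[j]) ** 2).sum())
    pairs = [dist[i, j] for i in range(n) for j in range(i + 1, n)]
    h = float(np.median(pairs))
    sigma = np.ones((n, n)) if h <= 0 else np.exp(-(dist**2) / (2 * h * h))
    sigma = sigma + ridge * np.eye(n)
    # explicit Moore-Penrose via SVD
    Us, ss, Vts = np.linalg.svd(sigma)
    cutoff = max(sigma.shape) * np.finfo(float).eps * ss.max()
    s_inv = np.array([1.0 / x if x > cutoff else 0.0 for x in ss])
    pinv = (Vts.T * s_inv) @ Us.T
    W = np.array([pinv[i, :].sum() for i in range(n)])
    return W / W.sum()


class TestExtractFeatures:
    def test_deterministic(self, latent_small):
        latent, wm, _ = latent_small
        a = extract_features(latent, wm)
        b = extract_features(latent, wm)
        np.testing.assert_array_equal(a, b)
        assert len(a) == len(FEATURE_NAMES)

    def test_constant_region_has_zero_sd_and_entropy(self):
        data = np.zeros((10, 10, 10))
        data[2:8, 2:8, 2:8] = 5.0
        mask = Volume((data > 0).astype(float))
        feats = dict(zip(FEATURE_NAMES, extract_features(Volume(data), mask)))
        assert feats["sd"] == 0.0
        assert feats["entropy"] == 0.0

    def test_sphere_volume_feature(self):
        r = 10.0
        g = np.mgrid[0:32, 0:32, 0:32].astype(float)
        dist = np.sqrt(((g - 15.5) ** 2).sum(axis=0))
        mask = Volume((dist <= r).astype(float))
        feats = dict(zip(FEATURE_NAMES, extract_features(Volume(np.ones((32, 32, 32))), mask)))
        assert feats["volume_voxels"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.02)

    def test_empty_mask_raises(self):
        with pytest.raises(VolumeError, match="empty"):
            extract_features(Volume(np.ones((4, 4, 4))), Volume(np.zeros((4, 4, 4))))


class TestComputeSimilarityWeights:
    def test_normalized_weights_sum_to_one(self, rng):
        F = FeatureMatrix(rng.normal(0, 1, (7, 30)), [f"f{i}" for i in range(30)])
        sw = compute_similarity_weights(F)
        assert abs(sw.normalized.sum() - 1.0) < 1e-10

    def test_mirrored_pair_splits_evenly(self):
        rng = np.random.default_rng(0)
        row = rng.normal(0, 1, 12)
        F = FeatureMatrix(np.vstack([row, -row]), [f"f{i}" for i in range(12)])
        sw = compute_similarity_weights(F)
        np.testing.assert_allclose(sw.normalized, [0.5, 0.5], atol=1e-10)

    def test_permutation_equivariance(self, rng):
        X = rng.normal(0, 1, (6, 25))
        names = [f"f{i}" for i in range(25)]
        nw = compute_similarity_weights(FeatureMatrix(X, names)).normalized
        perm = rng.permutation(6)
        nw_p = compute_similarity_weights(FeatureMatrix(X[perm], names)).normalized
        np.testing.assert_allclose(nw_p, nw[perm], atol=1e-9)

    def test_duplicate_subject_is_deweighted(self, rng):
        X = rng.normal(0, 1, (6, 25)) * rng.uniform(1, 50, 25)
        names = [f"f{i}" for i in range(25)]
        before = compute_similarity_weights(FeatureMatrix(X, names)).normalized
        X_dup = np.vstack([X, X[0]])
        after = compute_similarity_weights(FeatureMatrix(X_dup, names)).normalized
        # the duplicated subject loses weight, absolutely and within the run
        assert after[0] < before[0]
        assert after[0] == pytest.approx(after[6], abs=1e-9)
        assert after[0] < after[1:6].min()

    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(0, 1, (7, 40)) * rng.uniform(0.5, 20, 40)
        sw = compute_similarity_weights(FeatureMatrix(X, [f"f{i}" for i in range(40)]))
        oracle = brute_force_weights(X)
        np.testing.assert_allclose(sw.normalized, oracle, atol=1e-10)

    def test_near_duplicate_cluster_gets_smallest_weights(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 30)
        X = np.array(
            [base + rng.normal(0, 0.05, 30) for _ in range(4)]
            + [base + rng.normal(0, 1.0, 30) for _ in range(3)]
        )
        sw = compute_similarity_weights(FeatureMatrix(X, [f"f{i}" for i in range(30)]))
        assert sw.normalized[:4].max() < sw.normalized[4:].min()

    def test_all_constant_features_rejected(self):
        F = FeatureMatrix(np.ones((4, 5)), [f"f{i}" for i in range(5)])
        with pytest.raises(ValueError, match="zero variance|variation"):
            compute_similarity_weights(F)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            FeatureMatrix(np.ones((1, 5)), [f"f{i}" for i in range(5)])

    def test_component_cap_respected(self, rng):
        F = FeatureMatrix(rng.normal(0, 1, (10, 50)), [f"f{i}" for i in range(50)])
        sw = compute_similarity_weights(F, max_components=5)
        assert 1 <= sw.n_components_kept <= 5

    def test_clip_negative_renormalizes(self, rng):
        X = rng.normal(0, 1, (7, 30))
        sw = compute_similarity_weights(
            FeatureMatrix(X, [f"f{i}" for i in range(30)]), clip_negative=True
        )
        assert np.all(sw.normalized >= 0)
        assert abs(sw.normalized.sum() - 1.0) < 1e-10


class TestUniformWeights:
    def test_uniform(self):
        uw = uniform_weights(5)
        np.testing.assert_allclose(uw.normalized, 0.2)


class TestPopulationFeatures:
    def test_phantom_cluster_deweighted_end_to_end(self):
        from atlasforge.phantom import PhantomSpec, make_population

        spec = PhantomSpec(
            shape=(32, 32, 32), n_subjects=6, seed=3,
            deformation_amplitude=4.0, smoothness=5.0, noise_sd=1.0,
            cluster_spec=[(3, 0.5), (1, 0.0), (1, 0.0), (1, 0.0)],
        )
        pop = make_population(spec)
        sw = compute_similarity_weights(features_from_population(pop.subjects))
        assert sw.normalized[:3].mean() < sw.normalized[3:].mean()
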