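"""Patch-based mean-shift fusion: initializers, patches, steps, convergence."""

import numpy as np
import pytest

from atlasforge.core import Volume
from atlasforge.fusion import (
    FusionConfig,
    FusionState,
    extract_patches,
    mean_shift_step,
    median_init,
    nonzero_indices,
    run_fusion,
    voxel_mean_fusion,
)


def brute_force_step(template, aligned, radius=1, kernel="d2_over_2h2"):
    """Triple-loop reference: per voxel, per image, per patch offset."""
    data = template.data
    V = np.argwhere(data != 0)
    n = len(aligned)
    out = data.copy()
    offs = range(-radius, radius + 1)
    for (x, y, z) in V:
        tpatch, ipatches = [], [[] for _ in range(n)]
        for dx in offs:
            for dy in offs:
                for dz in offs:
                    u, v, w = x + dx, y + dy, z + dz
                    inb = (0 <= u < data.shape[0] and 0 <= v < data.shape[1]
                           and 0 <= w < data.shape[2])
                    tpatch.append(data[u, v, w] if inb else 0.0)
                    for i in range(n):
                        ipatches[i].append(aligned[i].data[u, v, w] if inb else 0.0)
        D = np.array([
            np.sqrt(sum((a - b) ** 2 for a, b in zip(tpatch, ipatches[i])))
            for i in range(n)
        ])
        h = np.median(D)
        if h == 0:
            wts = (D == 0).astype(float)  # kernel limit as h -> 0
        elif kernel == "d2_over_2h2":
            wts = np.exp(-D**2 / (2 * h * h))
        elif kernel == "d2_over_h":
            wts = np.exp(-D**2 / h)
        else:
            wts = np.exp(-D / (2 * h))
        nw = wts / wts.sum()
        out[x, y, z] = sum(nw[i] * aligned[i].data[x, y, z] for i in range(n))
    return out


class TestInitializers:
    def test_median_of_single_image_is_identity(self, rng):
        vol = Volume(rng.uniform(0, 100, (6, 6, 6)))
        np.testing.assert_array_equal(median_init([vol]).data, vol.data)

    def test_median_rejects_outlier_mean_does_not(self):
        vols = [Volume(np.full((4, 4, 4), v)) for v in (10.0, 10.0, 100.0)]
        assert median_init(vols).data[0, 0, 0] == 10.0
        assert voxel_mean_fusion(vols).data[0, 0, 0] == pytest.approx(40.0)

    def test_even_n_midpoint_convention(self):
        vols = [Volume(np.full((3, 3, 3), v)) for v in (10.0, 20.0, 30.0, 40.0)]
        assert median_init(vols).data[1, 1, 1] == pytest.approx(25.0)

    def test_voxel_mean_matches_loop_oracle(self, rng):
        vols = [Volume(rng.uniform(0, 100, (5, 5, 5))) for _ in range(4)]
        fused = voxel_mean_fusion(vols)
        expect = np.zeros((5, 5, 5))
        for v in vols:
            expect += v.data
        np.testing.assert_allclose(fused.data, expect / 4, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            median_init([])
        with pytest.raises(ValueError):
            voxel_mean_fusion([])


class TestExtractPatches:
    def test_interior_constant_patch(self):
        vol = Volume(np.full((6, 6, 6), 5.0))
        patches = extract_patches(vol, np.array([[3, 3, 3]]), radius=1)
        np.testing.assert_array_equal(patches, np.full((1, 27), 5.0))

    def test_corner_patch_zero_padding(self):
        vol = Volume(np.full((6, 6, 6), 7.0))
        patches = extract_patches(vol, np.array([[0, 0, 0]]), radius=1)
        # a corner has 2^3 = 8 in-grid neighbors; 19 padded zeros
        assert (patches[0] == 0).sum() == 19
        assert (patches[0] == 7.0).sum() == 8

    def test_deterministic_ordering(self, rng):
        vol = Volume(rng.uniform(0, 10, (8, 8, 8)))
        V = np.argwhere(vol.data > 5)
        np.testing.assert_array_equal(
            extract_patches(vol, V), extract_patches(vol, V)
        )

    def test_out_of_bounds_indices_rejected(self):
        vol = Volume(np.ones((4, 4, 4)))
        with pytest.raises(IndexError):
            extract_patches(vol, np.array([[4, 0, 0]]))


class TestMeanShift:
    def test_identical_inputs_converge_immediately(self, rng):
        data = rng.uniform(1, 100, (8, 8, 8))
        vols = [Volume(data.copy()) for _ in range(5)]
        template, deltas = run_fusion(vols, FusionConfig())
        assert len(deltas) == 1
        assert deltas[0] == 0.0
        np.testing.assert_array_equal(template.data, data)

    def test_outlier_patch_downweighted_in_limit(self):
        """Center intensities {50, 50, 90}, patch distances {0, 0, big}:
        the update stays at 50 + epsilon."""
        shape = (7, 7, 7)
        base = np.full(shape, 50.0)
        out = np.full(shape, 90.0)
        out[3, 3, 3] = 90.0
        vols = [Volume(base.copy()), Volume(base.copy()), Volume(out)]
        t0 = median_init(vols)  # == 50 everywhere
        state = FusionState(template=t0, V=nonzero_indices(t0))
        new_state, _ = mean_shift_step(state, vols, FusionConfig())
        updated = new_state.template.data[3, 3, 3]
        assert 50.0 <= updated < 50.5

    @pytest.mark.parametrize("kernel", ["d2_over_2h2", "d2_over_h", "d_over_2h"])
    def test_vectorized_step_matches_brute_force(self, rng, kernel):
        shape = (10, 10, 10)
        vols = []
        for _ in range(4):
            data = rng.uniform(10, 100, shape)
            data[rng.uniform(size=shape) < 0.2] = 0.0  # some zeros in subjects
            vols.append(Volume(data))
        t0 = median_init(vols)
        state = FusionState(template=t0, V=nonzero_indices(t0))
        cfg = FusionConfig(kernel_form=kernel)
        stepped, _ = mean_shift_step(state, vols, cfg)
        expect = brute_force_step(t0, vols, kernel=kernel)
        np.testing.assert_allclose(stepped.template.data, expect, atol=1e-10)

    def test_fused_values_stay_in_population_range(self, small_population):
        vols = small_population.subjects
        template, _ = run_fusion(vols, FusionConfig())
        stack = np.stack([v.data for v in vols])
        lo, hi = stack.min(axis=0), stack.max(axis=0)
        assert np.all(template.data >= lo - 1e-9)
        assert np.all(template.data <= hi + 1e-9)

    def test_iteration_cap_respected(self, small_population):
        cfg = FusionConfig(max_itr=5, tol=1e-30)
        _, deltas = run_fusion(small_population.subjects, cfg)
        assert len(deltas) == 5

    def test_terminates_within_default_cap(self, small_population):
        _, deltas = run_fusion(small_population.subjects, FusionConfig())
        assert len(deltas) <= 200

    def test_deterministic(self, small_population):
        a, da = run_fusion(small_population.subjects, FusionConfig())
        b, db = run_fusion(small_population.subjects, FusionConfig())
        np.testing.assert_array_equal(a.data, b.data)
        assert da == db

    def test_voxels_outside_v_keep_zero(self, small_population):
        template, _ = run_fusion(small_population.subjects, FusionConfig())
        t0 = median_init(small_population.subjects)
        assert np.all(template.data[t0.data == 0] == 0.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(patch_radius=0)
        with pytest.raises(ValueError):
            FusionConfig(tol=0.0)
        with pytest.raises(ValueError):
            FusionConfig(kernel_form="gaussian")
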