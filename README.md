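# atlasforge

Structurally unbiased brain-template construction for small, possibly
asymmetric MRI cohorts — similarity weighting, weighted symmetric model
construction (SMC), and patch-based mean-shift intensity fusion, with the
evaluation metrics to show that it worked.

## The problem

A brain template (atlas) is the common reference space a cohort's scans are
registered to.  Averaging a small cohort naively produces a template that
(i) drifts toward whichever anatomy happens to be over-represented, and
(ii) is blurred and outlier-sensitive, because voxelwise averaging mixes
misaligned edges and corrupted intensities.  `atlasforge` implements a
construction that addresses both, for researchers building
population-specific templates from modest numbers of preprocessed
(skull-stripped, intensity-normalized, co-gridded) T1-weighted volumes, and
a synthetic phantom generator so the whole pipeline is testable with known
ground truth and no data download.

## The method

**Similarity weights.**  From per-subject image features (first-order
statistics, shape descriptors, regional block means — or any feature matrix
you supply), z-score and project to the top principal components, build the
N×N subject-similarity matrix Σ (Gaussian kernel of score distances +
ridge), and set

    W_i = Σ_j (Σ⁺)_ij ,   NW = W / Σ_i W_i .

Near-duplicate subjects split the weight one of them would have had; a
subject unlike the rest keeps full weight.

**Weighted SMC.**  Register a reference subject I_j to every other subject
(pairwise displacement fields d_ji, pull-back, voxel units) and warp it by

    dw_j = Σ_{i≠j} d_ji · NW_i

to obtain the structural center I_wc in one shot — no iterative template
averaging.  Uniform weights recover plain SMC exactly.  All subjects are
then registered to I_wc, giving the aligned stack I′ and fields d_ic.

**Patch-based mean-shift fusion.**  Initialize T₀ as the voxelwise median
of I′; then iterate over T₀'s nonzero voxels: weight each subject by a
Gaussian kernel exp(−D²/2h²) of its 3×3×3 patch distance D to the current
template (h = per-voxel median distance), update the voxel to the weighted
average of subject intensities, and stop when ‖T_t − T_{t−1}‖₂ < 1e-6 or
after 200 iterations.  This seeks the mode of the local intensity
distribution: sharper edges, less outlier influence than the voxel mean
T_V.

**Metrics.**  WD (similarity-weighted squared displacement to the center —
structural bias), AGM (mean gradient magnitude — sharpness), NMC
(normalized Michelson contrast between pure WM and GM), D_KL
(template-vs-subject intensity divergence — outlier robustness), and mLJD
(mean log Jacobian determinant of subject→template deformations — how much
volume change a template demands).

## Worked example

```bash
atlasforge demo --seed 0 --out demo_run
```

generates the canonical asymmetric phantom population (48³ voxels, N = 7:
one 4-subject near-duplicate cluster, three singletons, one
intensity-shifted outlier), builds the weighted and unweighted centers,
fuses patch-based and mean templates, and prints (~45 s on one CPU):

```
wd_weighted_le_uniform: True
agm_patch_gt_mean: True
nmc_patch_ge_mean: True
dkl_patch_lt_mean: True
```

with the numbers behind them in `demo_run/summary.json`:

| quantity | weighted / patch | uniform / mean | meaning |
|---|---|---|---|
| WD (sum, voxel²) | 78 617.6 | 105 675.1 | the similarity-weighted center is less biased toward the duplicate cluster |
| AGM (foreground) | 9.450 | 9.391 | patch fusion keeps edges sharper than voxel averaging |
| NMC | 0.338 | 0.324 | higher WM/GM contrast |
| median D_KL vs clean subjects | 0.031 | 0.214 | the patch template tracks the population mode, not the outlier |

The cluster subjects received the smallest weights
(e.g. 0.006–0.093 for cluster members vs 0.16–0.38 for singletons in this
run), which is what pulls the weighted center off the over-represented
anatomy.

Every stage is also exposed on its own (`phantom`, `normalize`, `weights`,
`construct`, `fuse`, `evaluate`) and as a YAML-configured pipeline
(`atlasforge run --config cfg.yaml`), all reading/writing NIfTI, CSV, and
JSON.  Displacement fields are stored as 5-D vector NIfTI
(nx×ny×nz×1×3).

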