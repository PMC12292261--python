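# Methods

`atlasforge` builds a population-representative 3D brain template in two
stages — a *structure* stage that estimates the population's anatomical
center without iterative averaging, and an *intensity* stage that fuses the
aligned images robustly — and evaluates the result with five metrics.  This
note documents the model, the parameters that matter, the numerical
choices, and what the synthetic phantoms do and do not demonstrate.

## Data model

All images are 3D scalar `Volume`s on a common grid (RAS affine, voxel size
in mm).  Deformations are dense `DisplacementField`s in **voxel units**
with **pull-back** sampling: warping image *I* by *d* yields
*I(v + d(v))* at voxel *v*.  A single unit/convention is load-bearing
because the structure stage combines displacement fields by direct
voxel-wise weighted sums; any backend that produces mm-space or push-forward
fields must convert on ingestion.  Out-of-grid samples evaluate to 0
(skull-stripped background), and interpolated negatives are clamped to 0.

## Similarity weighting

To keep the center from drifting toward over-represented anatomy (clusters
of near-duplicate subjects), each subject receives a normalized weight
NW_i, with *smaller* weights for subjects that resemble many others:

1. extract a feature vector per subject: first-order intensity statistics,
   shape descriptors, and a 4×4×4 masked block-mean fingerprint (global
   histogram statistics are nearly invariant under smooth warps, so the
   regional block means carry the spatial information that texture features
   would otherwise provide);
2. z-score features across subjects, PCA, keep the fewest components
   reaching 95% explained variance, capped at 5;
3. form the N×N subject similarity matrix
   Σ_ij = exp(−‖s_i − s_j‖² / 2h²) + 0.25·δ_ij, with *h* the median
   pairwise score distance;
4. W_i = Σ_j (Σ⁺)_ij (Moore–Penrose pseudo-inverse row sums);
   NW = W / Σ W.

A block of k near-duplicates is a high-similarity block in Σ, and the
block's inverse splits the block's total weight among its members — an
exact duplicate halves its weight — while a distinct subject keeps full
weight.  Two design points deserve emphasis:

* **Why a kernel similarity matrix rather than a sample covariance of the
  scores.**  PCA scores are centered across subjects, so the all-ones
  vector lies *exactly* in the null space of any Gram or covariance matrix
  built from them; every pseudo-inverse row sum is then identically zero
  and normalization is undefined.  The kernel form keeps a unit-scale
  diagonal and strictly positive similarities, making the row sums
  well-conditioned at small N.
* **The ridge (0.25·I)** bounds the inverse when a duplicate block makes Σ
  singular; without it individual weights inside a near-duplicate block are
  numerically wild even though their block total is stable.  The ridge
  shrinks weights toward uniform, attenuating but never reversing the
  deweighting.

Negative weights remain possible; they are logged and, optionally
(`clip_negative`), clipped to zero and renormalized.  The degenerate cases
(all features constant; ΣW = 0) raise explicit errors.

## Weighted symmetric model construction

Pick a reference subject I_j (index 0 by default; any choice is valid and a
robustness check is part of the test suite), register it deformably to
every other subject to obtain pairwise fields d_ji, and form

    dw_j = Σ_{i≠j} d_ji · NW_i .

Weights are *not* renormalized over the i≠j subset: NW_j multiplies the
reference's implicit zero self-displacement, so uniform weights NW = 1/N
recover the unweighted symmetric-model mean exactly.  Warping I_j by dw_j
gives the (weighted) center; every subject is then registered to the center,
yielding the aligned stack I′ and the fields d_ic used by the bias metric.

Registration is a pluggable backend contract (`register(fixed, moving) →
voxel-unit pull-back field with warp(moving, d) ≈ fixed`).  The built-in
backend is multi-resolution symmetric-forces diffeomorphic demons
(SimpleITK filter inside a hand-rolled 3-level pyramid; shrink factors
4/2/1, smoothing sigmas 3/1.5/0.5 mm, 40/30/20 iterations, total-field
smoothing sigma 1.2 mm), which on 48³ phantoms recovers a known
amplitude-2 deformation to ≈0.2 voxel mean error in ≈1 s and is fully
deterministic.  An affine mode (12-DOF, mean-squares, full sampling for
determinism) backs the usability experiment's pre-alignment hook.
Subject-level registrations are pure functions run through an
order-preserving parallel map, so results are identical for any worker
count.

## Patch-based mean-shift fusion

The intensity stage starts from the voxelwise median T₀ of the aligned
stack and iterates, over the frozen set V of T₀'s nonzero voxels:

* extract the 3×3×3 patch of the current template and of every aligned
  image at each v ∈ V (zero-padded at the grid boundary so distances stay
  comparable);
* D_i(v) = ‖P_T(v) − P_I(i,v)‖₂;  h(v) = median_i D_i(v);
* w_i(v) = exp(−D_i²/2h²) (two alternative kernel exponents, exp(−D²/h)
  and exp(−D/2h), are selectable — the kernel's algebraic form is a
  documented choice, with the standard Gaussian as default);
* normalize the weights per voxel and set T(v) to the weighted average of
  the subjects' *center-voxel* intensities;
* stop when Δ = ‖T_t − T_{t−1}‖₂ (global L2 over the grid) < 1e-6 or after
  200 iterations.  Note the tolerance applies to an un-normalized norm, so
  convergence speed is grid-size dependent; a per-voxel-RMS mode is
  available but off by default.

Degenerate bandwidth h(v) = 0 means at least half the subjects' patches
match the template exactly; the kernel's h→0 limit is used (unit weight for
exact matches, zero otherwise), which reduces to a uniform average when all
subjects match and reproduces the intended outlier rejection when only some
do.  Where *every* patch matches, the template value is kept bit-exact so
identical inputs terminate at t=1 with Δ=0.  Every update is a convex
combination, so fused intensities stay inside the per-voxel population
range.  The voxelwise arithmetic mean (`voxel_mean_fusion`) is retained as
the comparison baseline.

## Intensity normalization (PLHM)

Piecewise linear histogram matching on the fixed [0, 100] scale: landmarks
are the 1st/99th percentiles (robust min/max anchors) plus the deciles
10–90, estimated on foreground (nonzero) voxels only.  Training rescales
each image's landmarks affinely to [0, 100] and averages across images;
application maps an image's own landmarks onto the standard ones piecewise
linearly, extrapolating the end segments before clipping to the bounds.
Background zeros map to exactly 0, and mapped foreground values are floored
just above 0 so the foreground set — and hence landmark estimation — is
stable under repeated application (idempotence holds to ~1e-3, limited by
order-statistic interpolation at landmark breakpoints).

## Evaluation metrics

* **WD** (bias): Σ_i (Σ_v ‖d_ic(v)‖²)·NW_i, reported as total and per-voxel
  average (voxel² units).
* **AGM** (sharpness): mean voxelwise gradient norm, central differences
  interior / one-sided at boundaries, over all M grid voxels by default.
  On desk-scale grids the whole-grid value is dominated by the averaged
  template's *boundary halo* (a thin ramp where subjects' brain outlines
  disagree) rather than by anatomical sharpness, so template comparisons
  use the optional brain-foreground mask.
* **NMC** (contrast): (WM_max − GM_min)/(WM_max + GM_min) over pure-tissue
  masks (inputs; the phantom provides ground-truth masks).
* **D_KL** (outlier robustness): Kullback–Leibler divergence in nats
  between foreground intensity histograms on shared edges (100 bins over
  the union range), with one Laplace pseudo-count per bin added to both
  histograms so empty bins never produce infinities.  Binning, background
  exclusion, and smoothing all change the number; none changes the
  patch-vs-mean ordering the tests assert.
* **mLJD** (usability): mean of ln |det(I + ∇d)| over the grid; 0 means
  volume-preserving registration, negative net compression.

## Synthetic phantoms and study conditions

The phantom module emulates *preprocessed* data: skull-stripped,
intensity-normalized brains on a common grid with exactly zero background.
A latent nested-ellipsoid anatomy (CSF shell / GM ring / WM core /
ventricles, class means ≈30/60/90, mild smooth texture) is warped by random
diffeomorphisms — Gaussian-filtered white-noise velocities integrated by
scaling and squaring (6 squarings), verified invertible via
min det(I+∇d) > 0 — then foreground Gaussian noise (clamped at 0), an
optional polynomial bias field, and an optional outlier (foreground
intensity shift, optional extra noise) are applied.  Cluster asymmetry:
subjects in a cluster share a base velocity and differ by small
perturbation velocities, so every true deformation is an exact
diffeomorphism and ground truth is available throughout.

Default study conditions (one CPU, minutes per run): 48³ grid, N = 7,
deformation amplitude 4 voxels (≈20% of the brain radius — post-affine
inter-subject variability; small enough amplitudes leave sub-voxel
deformations in which no center-estimation signal exists), velocity
smoothness 6 voxels, noise SD 1 on the 0–100 scale, asymmetric population
= one 4-subject cluster (intra-cluster amplitude 1) plus three singletons,
outlier = +15 foreground shift on a singleton.  Fusion-method comparisons
use a *residually misaligned* stack (amplitude-1 diffeomorphisms about the
latent anatomy plus noise and the outlier): this models the ~1-voxel
residual that deformable registration of real anatomy leaves, which is
precisely the regime where patch fusion and voxel averaging differ.  After
full demons alignment of these smooth phantoms the residual is ≈0.3 voxel
and the two fusion methods nearly coincide — a statement about phantom
simplicity, not about the estimator.

What passing phantom tests do **not** show about real data: no MRI physics
(no Rician noise, no partial-volume mixing), no cortical folding, no
scanner/protocol heterogeneity, and registration of nested ellipsoids is
far easier than of real brains.  The direction checks (weighted vs
unweighted bias; patch vs mean quality; matched vs mismatched usability)
transfer as *orderings*; the magnitudes do not.

## Known limitations

* The subject-similarity construction departs from a literal
  covariance-of-scores reading, which is identically degenerate (see the
  weighting section); the kernel matrix is the package's documented choice.
* Whole-image radiomics stand-in features are far weaker than a full
  texture catalogue; with very low contrast-to-noise the weighting can
  return near-uniform or mildly negative weights.
* Demons is adequate for smooth phantoms; real cohorts should plug a
  SyN-class backend into the registration contract.
* The fusion tolerance (1e-6 on a global L2 norm) effectively means "run
  to iteration cap" on large grids; use the RMS mode for grid-independent
  stopping.
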