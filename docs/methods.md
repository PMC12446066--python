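# Methods

`clemreg` registers a fluorescence-microscopy (FM) z-stack onto a volume
electron-microscopy (EM) stack of the same sample by aligning landmark
organelles that are visible in both modalities. The pipeline is fully
landmark-based: intensities are never compared across modalities, so the
stark contrast and resolution differences between FM and EM never enter the
optimization. This note records the model, the parameter choices, the
numerics, and what the bundled synthetic data can and cannot show.

## Pipeline model

1. **FM landmark segmentation** (`fmseg`). The landmark channel (typically a
   mitochondrial stain) is min–max normalized,
   `x_scaled = (x − x_min)/(x_max − x_min)`, and filtered with a difference
   of Gaussians, `G(σ₁) − G(σ₂)` with `σ₂/σ₁ = 1.6` — the classic
   approximation of the Laplacian of Gaussian for blob detection. The
   filter is applied separably; σ is expressed in pixels of the finest axis
   and the per-axis kernel width is scaled by the voxel size so the kernel
   has the same physical footprint along z as in xy (on isotropic data this
   reduces to a scalar σ). The response is thresholded slice by slice:
   voxel kept iff `response > T · mean(x_scaled over its slice)`. Because
   the per-slice mean intensity dims together with the signal as imaging
   depth increases, the cut automatically compensates depth attenuation.
   Two details matter and are configurable:
   * the statistic is computed on the *normalized input* slice, not on the
     DoG response. A purely response-relative statistic is scale-free in
     the noise, so slices containing no signal keep a fixed quantile of
     their own noise, and for sparse blobs it sits so far below the
     response peaks that `T ≈ 1.2` keeps the entire positive DoG lobe
     (several-fold dilation, instances merge). With the intensity
     reference, `T ≈ 1.2` acts as a genuine contrast cut. The
     response-based positive-part mean remains available
     (`dynamic_threshold(..., reference=None)`), plus an optional
     `floor_frac` guard that floors the slice statistic at a fraction of
     the volume statistic;
   * connected components (26-connectivity) outside the 5th–95th size
     percentile band are removed (`size_filter`), pruning speckle and
     over-merged clusters. Components exactly on a percentile boundary are
     retained.
   Defaults σ = 3.0, T = 1.2 suit FIB-SEM-style data; σ = 2.2, T = 1.3 suit
   noisier SBF-SEM-style acquisitions. `clip_overexposed` (Yen threshold,
   clipping rather than deletion) is available for channels with punctate
   saturation artifacts.

2. **EM landmark mask** (input). The EM instance segmentation is always an
   external input (in practice produced by a pretrained deep-learning
   model); the pipeline never computes it. When several candidate masks
   exist (e.g. from different preprocessing settings),
   `merge_masks_by_sum` merges them by summation, binarization and
   26-connected relabeling.

3. **Point-cloud sampling** (`cloud`). Both masks are brought onto a common
   isotropic grid (default: the EM voxel size). The pipeline resamples the
   *binarized* mask with linear interpolation and re-thresholds at 0.5,
   which places the resampled surface with subvoxel accuracy;
   nearest-neighbour label resampling staircases the FM surface at its
   coarse z-step (typically ≥ 100 nm) and measurably degrades registration
   (46 → 22 nm mean landmark error on the standard fixture when switching
   to the subvoxel path). A 2D Canny detector (σ = 1.0) run over every
   z-slice emits one point per membrane pixel, in a deterministic
   z-then-row-major order so downstream sampling needs no seed. The cloud
   is then reduced by (i) uniform downsampling — every k-th point, k = 30;
   (ii) voxel binning — one mean point per occupied 15³-pixel cell, grid
   anchored at the coordinate origin so FM and EM grids are commensurate;
   (iii) statistical outlier removal — drop points whose mean distance to
   their 20 nearest neighbours exceeds μ + 2σ of that statistic (parameters
   unspecified in the original protocol; these are common practice and
   exposed in the config).

4. **Registration** (`register`). Coherent point drift: the moving (FM)
   cloud provides the centroids of an isotropic Gaussian mixture, the fixed
   (EM) cloud is the data, plus an optional uniform outlier component of
   weight `w`. EM iterations alternate soft correspondences with
   closed-form updates — rotation from the SVD of the weighted
   cross-covariance (re-projected to det +1 every step), optional scale,
   translation, and the shared variance σ². Stops on |Δσ²| < 1e−6 or after
   50 iterations. Clouds are pre-centered internally for conditioning and
   the translation is recomposed on output. The recorded
   negative-log-likelihood trace is monotone non-increasing (the EM
   guarantee); σ² is recorded alongside. Three estimators are provided:
   * `RigidCPD` — rotation/scale/translation. The estimator defaults to
     estimating scale; the *pipeline* fixes scale = 1 because both clouds
     live on the same isotropic nm grid by construction, and letting scale
     float allows PSF-dilated FM surfaces to drag it below 1.
   * `AffineCPD` — closed-form linear M-step.
   * `NonrigidCPD` — the classic Gaussian-kernel coherent displacement
     field `v(y) = G(y,Y)W` with bandwidth β and motion-coherence penalty
     λ (λ→∞ recovers zero displacement). This is deliberately the classic
     nonrigid variant rather than the full Bayesian machinery: rigid
     alignment outperformed nonlinear on all benchmarks in the protocol
     this tool follows, so the nonrigid path is secondary. It is fitted in
     original (uncentered) coordinates so the stiffness limit holds
     exactly.
   Missing structure on the *fixed* side (e.g. EM instances the external
   model failed to segment) is tolerated gracefully — the corresponding
   mixture centroids are simply starved. Missing structure on the *moving*
   side leaves unexplained data and benefits from `w > 0`; note however
   that from a cold start with large initial σ² a large `w` can swamp the
   E-step normalizer and collapse σ² prematurely (a known trait of this
   family of implementations), so the default is `w = 0`.

5. **Warping** (`warp`). All warps are inverse-projection: every output
   voxel is sampled at the inverse-transformed location with spline
   interpolation (order 3 for affine warps, order 1 for TPS by default;
   out-of-grid samples interpolate against a zero exterior). The nonlinear
   path fits a 3D thin-plate spline with kernel φ(r) = r (the 3D biharmonic
   fundamental solution — the 2D r²·log r kernel does not transfer to
   volumes), solved exactly (zero regularization) so control points are
   interpolated to machine precision and an affine motion is reproduced
   with identically zero kernel weights. The field is fitted from
   registered-FM control points back to original FM space (inverse
   mapping). The output grid is processed as 2×2×2 sequential chunks to
   bound memory; evaluation is pointwise, so chunked and monolithic
   results are bit-identical. A coarse-lattice accelerator
   (`grid_step > 0`) evaluates the spline on a sub-sampled lattice and
   interpolates; the exact path is the reference. Finally the warped stack
   is resampled onto the EM grid.

6. **Evaluation** (`evalx`). Overlay quality is scored on *target*
   structures (e.g. lysosomes, 0.3–1 µm) that play no role in registration:
   intersected volume in µm³; Euclidean distance between marching-cubes
   mesh centroids (vertex mean — the simplest mesh-native statistic;
   volumes are zero-padded by one voxel so border-touching surfaces close);
   characteristic length L = V^(1/3) to compare error to structure size.
   Landmark-based scores: per-pair transformed-vs-fixed distances; a
   landmark-jitter experiment (Gaussian offsets, σ = n pixels per axis,
   seeded) comparing two transforms' error distributions with a two-sided
   pooled-variance Student's t-test; instance ablation (random, or
   peripheral/central by instance-centroid distance from the foreground
   centroid); and a Spearman correlation between each target's distance to
   the nearest landmark voxel (Euclidean distance transform) and its
   centroid error.

## The synthetic fixture

`synthgen` builds paired volumes with known ground truth so the whole
pipeline is testable offline. The default study conditions:

| quantity | default | rationale |
|---|---|---|
| EM grid | (72, 352, 352) @ 20 nm | flat adherent-cell-like slab, 1.4 × 7 × 7 µm |
| cell | ellipsoid, 0.46 of the grid per semi-axis | cropped acquisitions center the cell |
| landmarks | 40 ellipsoids, 300–500 nm diameter, 0.6–1.0 µm length, random orientation | literature mitochondrion sizes |
| separation | ≥ 150 nm between surfaces | landmarks must be resolvable in FM for any landmark-based method to apply; 150 nm is on the order of the xy resolution |
| targets | 5 spheres, 0.3–1 µm diameter | lysosome-sized evaluation structures |
| ground truth | rigid: 10° about z, 15 px translation | typical residual after orthogonal pre-alignment |
| FM grid | anisotropic (100, 40, 40) nm voxels | Airyscan-like sampling |
| PSF | Gaussian, FWHM (350, 120, 120) nm in (z, y, x) | the instrument's stated z / xy resolution; resolutions are FWHM, so σ = FWHM/2.355 |
| attenuation | ×exp(−0.005·z) per slice | the depth dimming the dynamic threshold exists to counter |
| noise | additive Gaussian σ = 0.05 (optional Poisson) | moderate-SNR organelle channel |

The FM stack is produced by pushing the EM-space geometry through the
*inverse* ground-truth transform onto the FM grid, blurring with the PSF,
attenuating, and adding noise — so the FM volume is anisotropic, blurred
and noisy while the EM volume is crisp, exactly mirroring the real data
layout. Instance centroids give paired held-out landmarks that no pipeline
stage ever sees. Target spheres exist in both modalities for evaluation.
Everything derives from a single seed; identical seeds give bit-identical
fixtures. Placement is rejection sampling, large structures first; a spec
too crowded to place fails loudly rather than degrading.

What the fixture does *not* emulate: real EM texture (membranes,
cristae — irrelevant here because the EM mask is an input), deformable
sample distortion (the truth transform is rigid/affine; the nonrigid path
is validated on synthetic smooth warps of point sets instead), FM
spectral cross-talk, and segmentation-model idiosyncrasies on the EM side.
Passing tests therefore demonstrate the geometry pipeline — segmentation,
sampling, registration, warping, scoring — under controlled optics, not
the performance of any particular EM segmentation model on real
micrographs.

## Numerical choices and degenerate inputs

* Axis order (z, y, x), 0-based, voxel centers on integer coordinates, all
  grids anchored at physical 0. Isotropic resampling maps new index i to
  old index i·(target/old); output shape is round(extent/target), min 1.
* Block binning crops each axis to the largest exact tiling before
  averaging, so intensity mass is conserved on tiling factors.
* Rigid CPD re-projects the rotation through the SVD with a sign-corrected
  last singular vector every M-step — reflections cannot occur. σ² is
  floored at 1e−12.
* Registration rejects clouds with < 3 points, non-finite coordinates, or
  rank-deficient (collinear) geometry.
* The TPS solve raises on coplanar or duplicate controls (condition number
  guard at 1e12) instead of returning a garbage field.
* Otsu segmentation of a constant region returns an empty mask; min–max
  normalization of a constant volume is an explicit error rather than NaN.
* A constant slice never passes the dynamic threshold for T ≥ 1 (its
  statistic equals its value).
* Statistical outlier removal on clouds smaller than the neighbour count
  warns and returns the cloud unchanged.

## Scale of the shipped experiments

The bundled robustness protocol (5 fixture seeds × 7 removal fractions ×
rigid CPD) and the end-to-end recovery run complete in a few minutes on one
CPU; cloud sizes after reduction are a few hundred points per modality.
These sizes were chosen so the full suite exercises every stage at
defaults; all of them scale up through the config without code changes.

## Known limitations

* Axis-aligned anisotropy only; oblique acquisitions must be resliced
  upstream (the real protocol pre-aligns to the nearest orthogonal
  rotation).
* The z accuracy of the overlay is bounded by the FM z-step and z-PSF:
  surfaces enter the clouds with ~100 nm z quantization, which leaves a
  systematic few-tens-of-nm z component in the landmark error even with a
  perfect segmentation. This mirrors the physics of the data, not a code
  limit.
* `w > 0.1` from a cold start can destabilize CPD (premature σ² collapse);
  pre-align first or keep w small.
* Per-z-slice Canny sampling leaves object top/bottom caps under-sampled;
  the z constraint comes from the ring-stack distribution instead.
* The percentile size filter always removes the largest ~5% of components;
  on data where large components are genuine (heavily merged masks), widen
  `size_pct_high`.
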