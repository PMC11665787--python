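# Methods

This note documents the models, estimators and numerical choices behind
`lusrecon`, what the synthetic phantom does and does not emulate, and the
limitations a user should know before applying the pipeline to real data.

## Coordinate conventions

All lengths are millimetres. Poses are 4×4 row-major homogeneous matrices
with orthonormal, det +1 rotation blocks (validated to 1e-6); every
pipeline output lives in the optical-tracker frame `O`. Ultrasound images
follow the B-mode convention: row index = axial depth with row 0 at the
transducer face, column index = lateral position, 0-based pixel centers.
`pixel_to_world` maps pixel `(col, row)` to
`(col·s_lat, row·s_ax + row0_offset, 0)` in the image frame `U` and then
through the frame's pose `T_U→O`. A configurable *gravity axis* of `O`
(default: +z, increasing downward) defines "vertical" for the surface fit
and displacement computation; aligning the tracker frame to gravity is the
caller's responsibility (on the phantom it holds by construction).

## Probe-pose estimation (PnP)

`pose_from_keypoints` minimizes the mean squared reprojection error over
the pose by Levenberg–Marquardt, initialized by a direct linear method:
a 12-parameter DLT for ≥ 6 non-coplanar keypoints, a homography
decomposition (in an arbitrary pattern plane basis) for coplanar ones, and
scale-derived frontal guesses as a fallback. Pose ambiguities are resolved
by lowest residual, then by all pattern points having positive depth.
Detections are assumed undistorted; `undistort_points` applies stored
radial coefficients by fixed-point iteration when needed. The RMS
reprojection residual in pixels is attached to the returned result.

## The pressure-compensation model

**Assumptions.** Probe pressure displaces tissue axially (per image
column), by an amount that equals the surface indentation `d` at the
contact line and decays to zero at the stress decay depth `c`:
`Δz(z) = d·exp(−z/(c−z))` for `z < c`, zero beyond. Lateral and
out-of-plane deformation are not modeled. The exponent's `(c − z)`
denominator makes the decay faster than exponential near `c`; the map
`z ↦ z − Δz(z)` has derivative `1 + d·c/(c−z)²·e^{−z/(c−z)} > 1`, so the
compensation warp is strictly increasing and invertible for any `d ≥ 0`,
`c > 0`.

**Reference surface.** The rest-shape liver surface is a bivariate
polynomial height field (default order 2, configurable) fitted by linear
least squares to 3D surface samples; the fit residual RMS is recorded. The
domain is the lateral bounding box of the samples; queries outside it are
evaluated at the clamped location and flagged invalid.

**Displacement profile.** For each frame, the contact line (image row 0
tracked into `O`) is compared with the reference surface vertically;
`d` per column is the contact height minus the surface height, clamped at
zero when the contact line lies above the surface (no indentation). Columns
outside the surface domain fall back to the frame's mean valid `d`.

**Decay-depth estimation.** SIFT features are matched between consecutive
frames (scikit-image `SIFT` + `match_descriptors` with cross-check and
ratio test), and outliers are removed by RANSAC under a 2D rigid motion
model (min 3 samples, 1.5–2 px residual threshold, fixed RNG for
determinism). Matched depths `p` are converted to mm by the axial spacing.
The estimator solves a bounded two-parameter nonlinear least-squares
problem for `(c0, c1)`: the de-shifted depth `p − Δz(p; d, c)` of a match
is its rest depth *below that frame's transducer face*, so the residual of
a match is the disagreement of the two rest depths **plus the face-height
offset** between the frames (known from the tracked poses; frames pressed
harder sit lower). Omitting that offset — i.e. comparing the de-shifted
depths directly — is exact only when both faces are at the same height and
introduces a systematic error of about `d0 − d1` otherwise. The piecewise
model (`Δz ≡ 0` for `p ≥ c`) keeps the objective smooth in `c` over the
whole bound interval, so matches at *all* depths participate: deep matches
anchor the rest depths where pressure is negligible, shallow ones carry
the decay signal. Optimization is multi-start (3 starts across the
bounds, lowest cost wins, default bounds 10–80 mm); a symmetric degenerate
match set (`p0 = p1`, `d0 = d1`) is detected up front and returns the
bounds midpoint with zero objective. When a frame pair yields fewer than 4
consensus inliers the pipeline holds the nearest-in-time estimate; if no
pair at all is estimable, `c` falls back to the imaging depth with the
convergence flag cleared.

Identifiability notes: the per-pair `(c0, c1)` problem is well-posed only
when the two frames differ in indentation — for `d0 = d1` the objective is
flat in `c` (the degenerate case above). In practice hand pressure varies
between frames, which is exactly what makes the estimator usable; the
phantom reproduces this with per-frame schedule jitter. With half-pixel
match noise at 0.1 mm/px axial sampling, median recovery error of `c` is
under 10% for 30 matches spread through the imaged depth; the warp itself
is much less sensitive to `c` than to `d`, so centerline accuracy degrades
gracefully with `c` error.

**Frame compensation.** Per column, the monotone map `g(z) = z − Δz(z)` is
inverted numerically (linear interpolation of `g` sampled at the pixel
grid) and the image is resampled at the original axial spacing on a canvas
extended upward by `max(d)`, so surface content restored above the
transducer face is kept; `row0_offset_mm` records the new origin and a
validity mask marks output pixels with no source content (excluded from
compounding). Estimation runs on every `decay_stride`-th frame pair
(default 5) — `c` varies smoothly between frames, and striding keeps a
100-frame sweep's SIFT cost at a few seconds.

## Compounding

Pixel-nearest-neighbor forward compounding: the grid (default 0.5 mm
isotropic, axes aligned with `O`) is anchored on the minimum of the
transformed pixel cloud; each pixel is accumulated into its nearest voxel
and voxel values are the running mean of their contributions (unbiased
under speckle; intensity mass `Σ value·count` is conserved exactly).
Remaining empty voxels with at least one filled neighbor within the fill
radius (default 1.5 mm, spherical) receive the neighborhood mean and are
flagged `hole_filled`.

## Overlay rendering

Segmented-structure boundary voxels are projected through the pinhole
model of a virtual camera with the laparoscope's intrinsics and splatted
far-to-near (painter's z-buffer) with a splat radius equal to the
projected voxel footprint; blending is standard alpha compositing
`out = (1 − α·a)·base + α·a·render`. Occlusion of internal structures by
the liver surface is not modeled — overlays show the vasculature as if the
organ were transparent.

## Evaluation

Vessel segmentations (on the phantom: intensity threshold 0.15 on the
compounded volume, connected components under 50 voxels discarded as
speckle) are thinned to a 3D skeleton (scikit-image), chained into
polylines between endpoints and junctions, and terminal spurs shorter than
3 mm are pruned. Curves are resampled at 0.5 mm arc length before distance
computation to remove vertex-density bias. The distance report pools
nearest-neighbor distances of both directions for mean/min/quartiles/
median/max and reports the classical symmetric Hausdorff distance (max of
the two directed maxima) explicitly alongside. PSNR is
`10·log₁₀(MAX²/MSE)` with an infinite sentinel for identical images; SSIM
is the standard 7×7 uniform-window formulation on the declared dynamic
range.

## The synthetic phantom

The generator emulates the geometry and failure modes the pipeline must
handle, not ultrasound physics. It builds a ~50×55×62 mm rest-shape volume
(0.5 mm voxels): smoothed-noise tissue texture around intensity 0.35, a
sinusoidal height-field surface (~5 mm deep, ±1 mm undulation, air above),
and three hypoechoic vessels (radii 1.6–2.5 mm, 10–20 mm below the
surface) with analytically known centerlines. The default sweep is 100
frames at 0.5 mm steps, 150×128 px images at 0.3 mm/px — a deliberately
reduced problem size that keeps a full pipeline run at a few seconds while
leaving every estimation problem (surface fit, matching, decay recovery,
skeletonization) non-trivial.

Deformation schedules: `d(t)` is a two-cycle sinusoid (1–5 mm commanded,
up to ~6 mm per column once surface curvature under the straight
transducer face is added) and `c(t)` a one-cycle sinusoid (22–38 mm), both
with per-frame Gaussian jitter (0.6 mm / 2 mm) representing varying hand
pressure — the frame-to-frame pressure difference is what makes the decay
depth identifiable. The forward deformation is the exact inverse of the
compensation map, applied axially per column (so compensation with the
true `(d, c)` recovers the rest slice up to interpolation error); an
optional model-mismatch mode substitutes a linear decay profile to test
robustness to the wrong functional form. Speckle is multiplicative
Rayleigh noise (unit mean) mixed at strength 0.25, followed by a 0.6 px
Gaussian blur and additive noise (σ = 0.01); measured poses carry 0.1° /
0.1 mm Gaussian noise by default. Surface samples (13×13 grid, 0.1 mm
height noise) stand in for points sampled manually on an intraoperative
scene reconstruction.

Not emulated: attenuation, shadowing, refraction and other acoustic
effects; lateral/out-of-plane deformation; elastic heterogeneity; camera
images of the probe pattern beyond projected keypoints. Passing tests on
the phantom therefore demonstrate correctness of the geometry and of the
estimation machinery under the stated deformation model, not clinical
accuracy.

## Numerical choices and degenerate inputs

- Chain composition validates adjacent frame labels and re-normalizes the
  homogeneous row exactly; empty labels act as wildcards.
- Surface fits reject rank-deficient designs (collinear samples); pattern
  geometries reject < 4 or collinear keypoints.
- `decay_shift` validates `z ≥ 0`, `d ≥ 0`, `c > 0`; the compensation loop
  asserts strict monotonicity of the warp (guaranteed analytically).
- Identical-image matching short-circuits RANSAC (exact-fit degeneracy).
- Single-voxel skeleton components become single-point branches flagged
  degenerate; empty labels return empty centerlines with a warning.
- All randomness (phantom, RANSAC, multi-start) is seeded; identical seeds
  give byte-identical simulated datasets and reports.

## Known limitations

- The decay-depth estimate is high-variance for individual frame pairs
  when indentations are similar; temporal holding between strided
  estimates trades responsiveness for cost.
- The compensation model is 1-D per column; probe tilt beyond a few
  degrees breaks the axial≈vertical approximation that links the
  displacement profile to the decay warp.
- Threshold-based vessel segmentation is a phantom convenience; real data
  needs a proper segmentation step in its place.
- Hole filling is an isotropic mean — it does not inpaint anisotropic
  speckle structure and can blur across vessel boundaries at large radii.
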