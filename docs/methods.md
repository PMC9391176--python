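# Methods

This note documents the models and procedures implemented in `ringsift`, the
parameter choices that matter, what the synthetic fixtures do and do not
emulate, and the numerical decisions a maintainer would want recorded.

## Pipeline model

The package implements a feature-matching pipeline for multi-view imagery —
detection, description, initial matching, mismatch removal — and a sparse
structure-from-motion reconstruction on top of it. Its assumptions are those
of classical sparse SfM: a pinhole camera with known (or approximated)
intrinsics `K`, a mostly rigid scene, and enough texture for repeatable
keypoints. Nothing in the pipeline is learned; every stage is deterministic
given its seed.

### Gradients

Gradients come from the 3×3 Sobel templates rather than SIFT's pixel
differences; Sobel combines smoothing with differentiation, which damps noise
and weakens unstable edge responses. Applied to a scale-space layer this
yields the first-order field (magnitude `√(Gx²+Gy²)`, direction
`atan2(Gy, Gx)`). A *second-order* field — Sobel applied again, to the
first-order magnitude raster — is what orientation assignment and descriptor
accumulation consume by default; a config switch (`descriptor_field`)
selects the first-order field instead. The magnitude raster is the only
scalar field the first-order stage defines, so it is the natural input for
re-differentiation. The printed form of the direction with arguments in the
order (horizontal over vertical) is treated as a typo: the quadrant-aware
`atan2(vertical, horizontal)` convention is used everywhere, and since the
descriptor only needs a *consistent* convention, the choice is unobservable.
Orientation at zero-magnitude pixels is defined as 0; those pixels carry zero
histogram weight, so this too is unobservable.

### Detection

Keypoint detection is deliberately classical: Gaussian pyramid with
`k = 2^(1/3)` scale steps, DoG extrema over 26 neighbors, quadratic
sub-pixel refinement, contrast threshold 0.03 (on intensities scaled to
[0, 1]), Hessian edge-ratio threshold 10, 36-bin orientation histogram over
a Gaussian-weighted disc of radius `3·1.5σ` with the 80% auxiliary-peak
rule. These are the standard published defaults; none of them is part of
this package's contribution. The pyramid starts at input resolution (no
initial 2× upsampling), so the default octave count is
`floor(log2(min(W,H)/16)) + 1` — a 256×256 image gets 5 octaves. Auxiliary
orientations duplicate the keypoint so each descriptor has exactly one
reference direction.

### Descriptor (8 rings × 8 bins = 64 dimensions)

The descriptor support is a disc of 8 concentric rings. Each pixel in the
disc contributes its gradient magnitude, multiplied by its ring's weight, to
an 8-bin orientation histogram of its gradient direction rotated by the
keypoint's main direction; contributions interpolate linearly between the
two adjacent bins; the 64-vector (ring-major) is unit-normalized. Choices the
underlying description leaves open, fixed here:

- **Ring weights**: a Gaussian falloff in the ring index,
  `w(r) = exp(−r²/(2·4²))`, normalized so ring 0 has weight 1. This satisfies
  the qualitative requirement (closer pixels matter more, all rings
  contribute) with one smooth parameter; the outermost ring keeps ~22%.
- **Ring width**: one pixel per ring on the keypoint's octave grid, scaled by
  the layer's relative scale (`ring_width = σ_oct/1.6` pixels), making the
  support scale-covariant. A config flag (`scale_with_sigma=False`) fixes it
  at exactly 1 pixel instead.
- **Boundary rule**: a pixel exactly on a ring boundary belongs to the inner
  ring (floor rule); a pixel at exactly the outer radius is excluded.
- **No clamp-and-renormalize**: a single unit normalization only (SIFT's 0.2
  clamping is a different design and is intentionally not replicated).
- The rings are plain circles; no affine/elliptical adaptation.

### Matching and neighborhood voting

Initial matching is exact nearest-neighbor search under
`arccos(⟨u,v⟩)` with the classic 0.8 ratio test, made one-to-one by keeping
the smallest-distance claim per target. The voting filter then checks
geometric consistency: for each candidate pair, the vector of distances from
its keypoint to all other matched keypoints — and likewise the vector of
wrapped main-direction differences mapped to [0, 2π) — should look the same
in both images. Both rows are unit-normalized and compared by
`dot = 1 − inner product`, a dissimilarity in [0, 2]; survival requires
`dot1 < T_d = 0.4` (distances) and `dot2 < T_θ = 0.3` (orientations). The
`1 −` convention is the interpretive keystone of the module: a raw inner
product of consistent rows is ≈ 1, so only as a dissimilarity do the small
thresholds make sense.

A property worth knowing: the distance term is intrinsically insensitive to a
*single* displaced match. Two all-positive unit vectors cannot have a
dissimilarity above roughly `1 − 1/√(1+cv²)` (cv = coefficient of variation
of the distances), about 0.1 for uniformly spread keypoints — far below
`T_d = 0.4`. In practice the orientation term does the discriminative work: a
false match carries an essentially random main-direction difference, which
shifts its whole orientation row and pushes `dot2` past 0.3. The planted-
mismatch tests encode exactly this behavior. Sets of ≤ 2 pairs have no
neighborhood to vote with and pass through with a logged warning.

### Trimmed RANSAC

Matches are already sorted by descriptor distance (best first); the worst
`floor(0.2·N)` are deleted before sampling — "distance" here is descriptor
distance, the only matching-quality order defined at this stage (image-space
distance between corresponding points is meaningless without a transform).
RANSAC then draws minimal 4-pair samples (rejecting collinear triples in
either image), fits a homography by DLT, scores with the symmetric transfer
distance at 2 px per direction, keeps the best consensus under adaptive
stopping (confidence 0.995, cap 2000 iterations), refits by normalized DLT
on the inliers and re-classifies until the inlier set is stable. The model
class is a plane-projective homography because a 4-point minimal sample
determines exactly that; for general 3-D scenes it is an approximate
mismatch filter, applied *before* (not instead of) fundamental-matrix
estimation.

One consequence is confronted explicitly in the reconstruction driver: on a
genuine 3-D scene the depth-induced parallax of off-plane points is itself
several pixels, so a 2 px homography filter keeps only the dominant plane —
and a single-plane correspondence set makes the fundamental matrix
degenerate. `reconstruct` therefore runs this stage with a threshold of at
least 2% of the image diagonal; the tight 2 px default remains in force for
pure matching, where the scene model *is* a homography.

### Two-view geometry and reconstruction

The fundamental matrix is estimated by the Hartley-normalized 8-point
algorithm inside RANSAC with Sampson-distance inliers (threshold 2 px) and a
final refit on all inliers; rank 2 is enforced by zeroing the smallest
singular value. The essential matrix is first formed as `E = K′ᵀFK` and then
re-fit by the same linear 8-point directly in K-normalized coordinates on
the inlier set. The second step matters: the `(s, s, 0)` singular structure
of E lives in normalized coordinates, and merely projecting an uncalibrated
F onto that manifold loses noticeable accuracy (on the synthetic rigs,
pixel-scale epipolar residuals and ~1° of extra pose error). Both steps are
linear least squares; there is no nonlinear refinement and no bundle
adjustment anywhere in the package.

Pose comes from the SVD of E (four candidates `{UWVᵀ, UWᵀVᵀ} × {±u₃}`,
`det R = +1` enforced) resolved by cheirality — the candidate placing the
most triangulated points in front of both cameras, voted on at most 50
correspondences for speed. Triangulation is the linear DLT on the 4×4 design
matrix; points at infinity (|w| below 1e−12 of the spatial part) are flagged
and excluded. Points must reproject within the configured ceiling and have
positive depth in every observing camera or they are dropped. The scale
convention is `‖T‖ = 1` for the first camera pair.

The third view is registered from 2-D–3-D correspondences of
already-triangulated points: linear DLT resection in normalized camera
coordinates inside RANSAC (6-point samples), projecting the linear estimate
onto the nearest rotation. Keypoints of the middle image are keyed by
position (not index) when intersecting the two match sets, because auxiliary
orientations duplicate keypoint indices. New tracks seen only by views 2–3
are triangulated and appended. No more than 3 views are supported, and no
global refinement is performed.

Degenerate inputs: identical or nearly identical views are rejected with a
low-parallax diagnostic (median correspondence displacement < 0.5 px);
RANSAC failures distinguish "too few matches" from "no consensus"; every
stage failure carries its stage name into the CLI report, which is
null-filled rather than truncated on failure paths.

## Synthetic fixtures: what they emulate, what they don't

- `make_texture` produces band-limited noise textures (single fine band by
  default; a four-band `multiband-noise` style for renderings that minify
  the texture), blob fields, and noisy checkerboards. The noise styles
  stretch contrast to the 2nd–98th percentile with clipping — the histogram
  shape of a photograph — rather than to the global extrema, which would let
  a single outlier pixel compress everyone else's contrast. They emulate
  *texture richness*, not the structured content of real photographs or
  ultrasound.
- `make_warp_pair` emulates viewpoint/appearance change with a known
  homography plus blur and gamma; a matched pair is *correct* iff the
  ground-truth warp moves the reference keypoint within 2 px of its partner
  (mirroring the RANSAC threshold, so "matching rate" is well defined).
  Real image pairs add occlusion, non-planar parallax, sensor noise and
  compression, none of which are modeled here — passing these fixtures shows
  geometric/photometric invariance of the descriptor chain, not performance
  on any particular real dataset.
- `make_rig` plants a unit-diameter point cloud observed by 2–3 cameras on
  an arc (11.5° default separation, depth ≈ 5 baselines) emulating a
  ~12-megapixel camera (4096 px wide, 6000 px focal): at that resolution,
  1 px of feature-localization noise is the realistic figure, and the pose
  information content supports sub-half-degree rotation recovery. On a
  0.5-megapixel sensor the same 1 px of noise is several times more angular
  error, and no estimator — linear or maximum-likelihood — recovers rotation
  to half a degree under those conditions; the camera model, chosen once, is
  the realistic one. The 2 px reprojection ceiling stated for ~0.5-Mpx
  imagery scales proportionally (16 px) on this camera in the rig-based
  tests.
- `make_two_plane_scene` renders a textured background plane plus a nearer
  foreground square through known cameras — the minimal scene with genuine
  depth structure that is still renderable exactly by homography warps. Its
  `backproject` method gives the true 3-D point behind any pixel, making the
  image-level reconstruction self-validating.

All generators are pure functions of their arguments including the seed.

## Numerical choices

- Sobel is applied as a correlation filter with edge replication
  (`scipy.ndimage.correlate`, mode `nearest`); an x-ramp gives interior
  response +8.
- Median filter: `scipy.ndimage.median_filter`, edge replication, default
  3×3 window (configurable, odd ≥ 3).
- Orientation histograms get two circular `[1,2,1]/4` smoothing passes
  before peak extraction; peaks interpolate parabolically.
- Homography normalization: `H[2,2] = 1` when that entry is nonzero, unit
  Frobenius norm otherwise; F is scale-normalized with `F[2,2] ≥ 0`.
- RANSAC ties (equal inlier counts) break toward the smaller total residual;
  all sampling uses `numpy.random.default_rng(seed)`, so fixed seed means
  bit-identical output.
- Collinearity in minimal samples: cross-product test with tolerance
  `1e−8 · extent²`.
- PLY output is binary little-endian (float32 xyz, optional uchar rgb) with
  a fixed header, so identical clouds give byte-identical files.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
deliberately modest sizes — 256² warp fixtures (10 seeds), 30-pair planted
outlier sets (100 seeds), 20 two-view rigs of 200 points, one 200-point
three-view rig, and one rendered 560² three-view scene — sizes at which the
full pipeline completes in seconds while every stage still operates in its
intended regime.

## Known limitations

- The homography-based mismatch filter assumes a dominant planar or
  quasi-planar relation between views; on strongly 3-D scenes it must be run
  with the relaxed threshold (done automatically in `reconstruct`), and even
  then it biases the surviving set toward lower-parallax matches.
- The voting filter's distance term barely discriminates (see above); its
  orientation term does not fire on mismatches that happen to preserve the
  main direction.
- No bundle adjustment: pose and structure are as good as the linear
  estimators allow; with only 2–3 views and no loop closure, errors grow
  with noise rather than being redistributed.
- Exact nearest-neighbor matching is quadratic in the number of descriptors;
  fine at fixture scale (hundreds of keypoints), not intended for
  thousands-of-features imagery.
- At most 3 views; no dense stereo, meshing, or texturing.
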