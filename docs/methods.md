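# Methods

## Problem

Given a contrast-enhanced CT (CTA) volume containing one unbranched vessel
(the aorta is the motivating case), produce simultaneously:

1. a per-voxel lumen probability mask, and
2. the vessel centerline as an **ordered polyline of real-valued 3D
   points** whose connectivity is fixed a priori (point *i* joins point
   *i+1*).

Because connectivity is structural, the output never needs skeleton
pruning, point linking, smoothing, or any other post-processing — the
defining property of the one-stage approach, and the property the test
suite verifies mechanically on every prediction.

## Model

The network has three parts sharing one encoder:

* **Encoder** — a stride-2 stem convolution followed by one MBConv block
  (inverted bottleneck: 1×1×1 expansion, 3×3×3 depthwise convolution,
  squeeze-excitation, 1×1×1 projection; SiLU activations) per stage. Five
  stages produce feature maps at downsampling factors 2–32; spatial sizes
  follow ceil-division, so any input with all axes ≥ 32 is legal.
* **Voxel decoder** — U-Net style: nearest-neighbor upsampling to the
  exact shape of the encoder skip, channel concatenation, then two
  conv/norm/ReLU blocks per level; a final upsample to full resolution and
  a 1×1×1 sigmoid head give the lumen probabilities. Normalization is
  instance-style by default (per sample, per channel) so batch-1 CPU
  inference matches training statistics; batch normalization is available
  via `NetworkConfig(norm="batch")`.
* **Centerline decoder** — five refinement stages, coarse to fine. Stage
  *s* samples point features from one map of the sampling pyramid (the
  coarsest encoder map, then the decoder maps at /16, /8, /4, /2) by
  trilinear interpolation at the current candidate coordinates. A linear
  head predicts `k = 4` auxiliary neighbor locations per point
  (tanh-bounded to one cell of that stage's grid); neighbor features are
  sampled and concatenated with the point's own features, its coordinates,
  and its normalized chain parameter *t = i/(P−1)*, then fused by a
  pointwise linear map. Two residual graph-convolution blocks
  (graph conv → SiLU → LayerNorm, twice, plus identity shortcut) propagate
  information along the chain, whose symmetric-normalized adjacency
  (self + predecessors/successors) is fixed. A zero-initialized graph-conv
  head emits coordinate offsets; outputs are clamped to the unit cube.

All decoder coordinates are **normalized**: world mm divided by the volume
extent per axis, so the unit cube is the field of view. The voxel-center
convention is `world = origin + (index + 0.5) · spacing` everywhere
(NIfTI, VTP, JSON, and in-memory).

### The initial polyline

The starting polyline (a random straight segment, endpoints uniform in
[0.2, 0.8]³, P equally spaced points) is drawn **once, when the model is
constructed**, from the model seed, and kept fixed for training and
inference. This matters: with a freshly randomized polyline per training
step the decoder must be robust to every possible start and, at the small
iteration budgets this package targets, fails to learn at all (it cannot
overfit even a single phantom in 150 iterations; with the fixed buffer it
does so in 50). Inference is consequently deterministic.

### Positional conditioning

Convolutional features are translation-equivariant: two co-located points
sample identical vectors, so a head shared across points would move
clustered points identically and a collapsed polyline could never spread
back along the vessel. Feeding the candidate coordinates and the chain
parameter into the fuse step breaks this symmetry and is what makes
coverage of the whole vessel learnable at small scale.

## Training loss

With `Mp/Mt` the predicted/target masks, `Cp/Ct` the predicted/target
centerlines (normalized coordinates):

* **Voxel loss**: focal + Dice,
  `L_vox = −Σ_i Σ_k Mt (1−Mp) log Mp − (2/|K|) Σ_k [Σ Mt Mp / Σ (Mt+Mp)]`,
  natural log, probabilities clamped to [1e-7, 1−1e-7]. The focal term
  vanishes wherever `Mt = 0`, so with only a lumen class nothing penalizes
  false positives and the mask dilates severely (observed: ×3 volume);
  the class set therefore includes the explicit background complement
  (`K = {lumen, background}`) during training. The public
  `voxel_loss(mp, mt)` with `class_axis=None` is the single-class form.
* **Chamfer distance** (final stage): symmetric sum of unsquared
  nearest-neighbor Euclidean distances between the predicted points and
  the GT curve resampled at 2 mm arclength (`squared=True` available).
* **Matched polyline loss** (intermediate stages): the GT resampled to P
  points arclength-uniformly; summed per-point Euclidean distance under
  the better of the two chain directions. This order-aware deep
  supervision assigns each point a unique target and converges an order of
  magnitude faster than all-stage Chamfer; `stage_supervision="chamfer"`
  restores the order-free variant. Because a tube has no intrinsic
  direction, the GT is oriented canonically once per case (its
  endpoint-to-endpoint vector flipped into a fixed half-space) so the
  matched targets cannot flip between training steps.
* **Edge-length regularizer** (final stage): sum of squared consecutive
  edge lengths; for fixed endpoints it is minimized by uniform spacing.
  A `variance_of_edges` alternative directly penalizes spacing spread.
* **Point-in-lumen regularizer** (final stage): the (single-class) voxel
  loss evaluated on mask probabilities trilinearly sampled at the
  predicted points against an all-ones target. The sampled probabilities
  are detached — a stop-gradient keeps the term from training the voxel
  head — but the point coordinates receive gradient through the
  interpolation weights, pulling stray points back into the vessel.
* **EMA normalization**: the voxel and lumen terms enter the total through
  `L̄ ← α L̄ + (1−α) L` with α = 0.9; only the current-step loss carries
  gradient (scaled by 1−α). The total is
  `L = L̄_vox + L_cd + L_elr + L̄_plr`. The training loop warm-starts each
  EMA at the first observed loss (a logged-value change only — the
  gradient is `(1−α)∇L` either way) so the reported total is on the raw
  scale from step one and decreases monotonically during an overfitting
  run. An alternative mode (`normalize_by_ema=True`) divides each raw
  loss by its detached running average; it measured worse on phantoms and
  is off by default.

Optimization: AdamW (lr 1e-3, weight decay 1e-4, my defaults beyond the
stated learning rate), batch 2, global gradient-norm clip 1.0, fully
seeded batch sampling (iteration *i* draws from `SeedSequence([seed, i])`
so interrupted runs resume bit-compatibly).

## Synthetic phantoms

The phantom generator is the package's stand-in for patient CTA data and
defines the study conditions of every experiment here:

* grid 48³ at 2 mm isotropic spacing (96 mm field of view);
* one unbranched tube per volume: mostly `aorta_like` (a half-circular
  arch, radius 16–30 mm, joined C1-smoothly to two straight descending
  limbs), with minorities of free-floating arcs (radius 40–80 mm) and
  straight segments; random 3D orientation (free spin about z, ±0.3 rad
  tilt);
* tube radius 8–15 mm, lumen 250–350 HU over a −30…+30 HU background,
  edge blur 0.5–1.5 mm (partial volume);
* ground-truth centerline sampled every 6 mm of arclength (≈ 20–30 points
  per case, matching the annotation density of radiologist-placed aortic
  centerline points).

The mask is the set of voxel centers within the tube radius of the
densely resampled curve, with flat end caps (so a straight tube has
volume πr²L — see the design note below). Rendering is two-level HU plus
Gaussian edge blur. Everything is reproducible per (seed, index).

What the phantoms do **not** emulate: branching topology, stenoses,
calcifications, wall/thrombus layers, surrounding anatomy (other organs
at similar HU), anisotropic spacing, and scanner noise texture
(only additive Gaussian noise is modeled). Passing the phantom
experiments therefore demonstrates that the method recovers unbranched
tubular geometry under the stated artifact models, not clinical-grade
aortic performance.

## Metrics

Volumetric Dice (percent, threshold 0.5; 100 when both masks are empty)
for segmentation. For centerlines, both polylines are resampled at a
0.5 mm arclength step (samples anchored at the first endpoint, final
endpoint appended — halving the step keeps all previous samples), each
sample is scored by its point-to-segment distance to the *opposite
polyline*, and the two directed distance sets are pooled:

* SD(τ): percent of pooled samples within τ (τ = 1 and 3 mm reported);
* HD95: 95th percentile (linear interpolation) of the pooled distances;
* ASSD: their mean.

These exact definitions (resampling step, segment distances, pooled
percentile) are fixed here so numbers are comparable across runs of this
package. Aggregation over cases reports mean ± population SD.

The classical mass-centroid baseline (per-axial-slice foreground centroid,
ordered by slice) is included as an oracle: exact to within half a voxel
on straight axis-aligned tubes, and degrading on oblique geometry — an
axial slice cuts an arch non-perpendicularly (and may cut it twice, which
raises a warning) — which the tests confirm directionally.

## Perturbations

Intensity artifacts (ground truth untouched): additive Gaussian noise of
variance 15 HU² (reading "variance of 15 HU" as HU²; σ ≈ 3.87 HU,
configurable), a single global calibration shift uniform in ±10 HU, and
linear motion blur (normalized line kernel spanning an amplitude of 1–3
voxels along a random or given direction, rendered by trilinear splatting;
support = amplitude+1 voxels on-axis).

Geometric transforms move image, mask and centerline with the same map:
similarity transforms (scale 0.9–1.1, rotations ≤ 10°) resample the image
with cubic B-spline interpolation, the mask with Gaussian smoothing
(σ = 1 voxel) + linear resampling + 0.5 threshold, and map GT points
analytically; grid distortion builds a smooth displacement field from a
4³ control grid (≤ 4 mm, boundary pinned, cubic upsampling), moves GT
points by the forward field, warps the image through the fixed-point
inverse, and rejects folding fields (non-positive Jacobian determinant).
Exact identity transforms short-circuit to a copy. The magnitudes are this
package's choices; tests check Jacobian positivity across 100 seeds and
GT containment after every augmentation.

## Numerical and design notes

* **No GPU framework**: the tensor engine (`vesseltrace.nn.autodiff`) is a
  compact reverse-mode autodiff over float32 numpy arrays; conv3d is
  im2col + BLAS matmul with "same-ceil" padding, the depthwise conv is an
  einsum over strided windows, upsampling adjoints use `add.reduceat`,
  and trilinear sampling is differentiable in features and coordinates
  (coordinate gradient zero in the border-clamped region).
* **Tube end caps**: a tube defined as {distance to curve ≤ r} carries
  hemispherical caps (+4r/3L relative volume, ≈ 11 % at aortic
  proportions). The rasterizer cuts flat caps at the end planes so the
  analytic-cylinder volume check is meaningful; the price is that the two
  endpoint GT points lie on the mask boundary.
* **Chamfer at zero distance**: the engine's sqrt backward floors its
  denominator, which bounds the Chamfer subgradient by the unit vector at
  coinciding points; forward values are exact.
* **Problem sizes**: the canonical experiment trains the tiny preset
  (channels [8,16,24,32,48], 32 points) on 64 phantoms for 500 iterations
  of batch 2 and evaluates 16 held-out phantoms — sizes chosen so the full
  pipeline runs on a single CPU core in minutes while still exercising
  every component at realistic geometry. The study-scale preset
  (EfficientNetV2-b0-like widths, 96 points, 80 × 1000 iterations) is
  configured but not exercised by the test suite.

## Known limitations

* Unbranched topology only; the chain adjacency is fixed (the
  k-NN/spanning-tree extensions discussed in the literature are out of
  scope).
* At the tiny scale the two heads converge at very different rates:
  segmentation saturates within ~200 iterations (VD 95–98 %), while the
  centerline is still mid-optimization at 500 iterations — held-out SD-3
  typically lands between 55 and 75 % with a run-to-run spread of about
  ±10 points, reaching the 80s when the budget is doubled. The dominant
  residual error is under-extension: the chain stops a few voxels short
  of the tube ends, because vessel extent is not inferable from local
  mid-tube features, and the lumen regularizer penalizes even a correctly
  placed endpoint (the interpolated mask probability on an end face is
  0.5). Deeper encoders and several loss reweightings were evaluated and
  converge *more slowly* at this budget; the shipped configuration is the
  best of those examined.
* The matched-polyline deep supervision and the positional conditioning
  of the fuse step are this package's additions for small-budget
  trainability; at study scale with ~10⁵ iterations order-free Chamfer
  supervision of every stage may suffice (`stage_supervision="chamfer"`).
* NIfTI affines are restricted to axis-aligned positive-diagonal; DICOM
  and oblique acquisitions are out of scope.
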