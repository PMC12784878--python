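# Methods

This note documents the models, conventions and numerical choices behind
`sowmorph`, and what the synthetic validation does and does not show.

## Problem setting

A depth camera mounted ~2.1 m above a single-sow stall records top-view
depth rasters (400 x 240 px, focal length 215.9346 px, depth in mm).
The goal is non-contact morphometry: per animal, estimate body weight
(BW, kg) and five linear sizes — chest width (CW), hip width (HW), body
length (BL), chest height (CH), hip height (HH), all in cm.  The
pipeline is: depth raster → point cloud → back segmentation (back = 1,
everything else including head, tail, floor and stall rails = 0) →
multi-output regression on the segmented back cloud → optional per-point
saliency map.

## Depth to point cloud

Pinhole back-projection per valid pixel:

    x = D (u - cx)/fx,   y = D (v - cy)/fy,   z = D,

camera frame +x right, +y down, +z away; units mm throughout.  Depth is
taken as z-depth (the native output of stereo depth sensors) rather than
range along the ray.  The principal point defaults to the frame centre
(the sensor model states only the focal lengths; without centring, the
reconstructed scene would be entirely one-sided, contradicting the
centred geometry of the stall).  Depth 0 is the dropout convention of
this sensor family and is treated as invalid, never zero-filled.

## Synthetic scene generator

The generator is the package's study population: every training or
evaluation run draws from it, so its defaults matter.

**Geometry.** The back is a superellipsoid-like half shell over the
floor.  Along the body axis s in [0, 1] (chest at s = 0), the
cross-section half-width interpolates linearly CW/2 → HW/2 and the ridge
height CH → HH plus an optional arch term `spine_arch * sin(pi s)`
(default uniform 0–40 mm across animals).  The cross-section profile is
a superellipse with exponent 2.5 (rounder than an ellipse near the
ridge, steeper at the flanks — the visual shape of a sow's back).  Head
and tail are ellipsoidal cap extensions of the end cross-sections (18%
and 12% of BL) rendered but labeled background, because the measurement
target is the back without head and tail.  Two stall rails (40 mm wide,
1100 mm above floor, at ±350 mm) occlude from above; the floor sits at
the camera height.

**Rendering.** Each pixel's depth is the first intersection of its ray
with the scene, found by a coarse march (~6 mm steps, far below any
feature size) followed by 48 bisection iterations.  Noiseless body
points therefore lie on the analytic surface to < 1e-9 mm, which the
test suite asserts; a splatting renderer would not have this property.
Gaussian depth noise (default sd 5 mm, a realistic stereo-depth figure
at 2 m range) is added to the raster before back-projection; dropout
(default 2%) invalidates pixels.

**Population.** Default parameter distributions reproduce the reference
label statistics of the housed-sow population the package targets:
BW 211.5 ± 20.8 kg, CW 36.4 ± 2.5, HW 36.9 ± 2.5, BL 86.6 ± 2.7,
CH 90.1 ± 5.6, HH 84.6 ± 2.5 cm.  Dimensions share a latent size factor
with loading 0.554: independent per-dimension draws would give the
weight proxy a dispersion of only ~14 kg; the loading was solved
analytically (once, then frozen) so that each dimension keeps its
mean/sd exactly while the weight proxy reproduces the 20.8 kg sd.

**Weight label.** No weight–shape law is observable from a depth image,
so BW is defined by a fixed allometric volume proxy

    BW = c * sqrt(CW * HW) * BL * (CH + HH)/2        [cm -> kg]

with c calibrated once so the population-mean shape weighs 211.5 kg.
The proxy is cubic in linear dimension and smooth and monotone in every
size — sufficient for recovery testing; it is not a husbandry-grade
weight model.

**Hierarchy.** Datasets are subjects → measurement sets → frames: shape
drawn once per subject, a ±1% multiplicative growth jitter per set
(repeated measurements weeks apart), pose jitter per frame (yaw sd 8°,
lateral sd 40 mm, longitudinal sd 60 mm).  All frames of a set share the
set's labels exactly.  Seeding is hierarchical via `SeedSequence`
spawning, so any subset regenerates identically.  The study-scale
configuration is 60 subjects x 4 sets x 50 frames = 12,000 frames.

**What it does not emulate.** Articulated limbs and posture changes,
lying animals, occlusion by pen furniture other than rails, multi-animal
scenes, RGB texture, and sensor artefacts beyond i.i.d. Gaussian noise
and dropout.  Passing the recovery studies therefore shows the
architectures can extract metric information from top-view back
geometry under noise; it does not certify field accuracy on real sows.

## Segmentation network

A compact kernel-point-convolution encoder–decoder.  A kernel point
convolution aggregates neighbour features with weight matrices attached
to 15 frozen 3D kernel points (one central, fourteen repulsion-arranged
on a 0.66-radius shell), with linear influence `max(0, 1 - d/sigma)`
and spherical neighbourhoods of radius r.  Three encoder levels
(channels 32/64/128) each downsample by 1/4 via farthest point
sampling; radii are 2.5/5/10 x the cloud's mean point spacing with
sigma = r/2; the decoder upsamples by nearest neighbour with skip
concatenation and pointwise layers back to per-point logits.  The
middle level uses deformable kernels: per-centre offsets predicted by a
rigid kernel convolution, smoothly bounded to ±sigma by a tanh clip,
with a mean-squared-offset regulariser (weight 0.1) — the deformation
needs some penalty to stay local, and none is prescribed, so the
simplest one is used.  Input features are a constant 1 plus the centred
z coordinate in metres ("height" mode; a pure constant-1 mode exists).
Cross-entropy uses inverse-class-frequency weights because floor pixels
dominate top views.

## Regression network

The dual-branch regressor maps a segmented back cloud (n x 3, default
n = 1024, random seeded subsample if larger) to the six metrics.

* **Input convention.** Clouds are centred at their centroid and
  converted mm → m.  This is a fixed global unit change applied
  identically to every sample, so absolute body size stays encoded;
  per-sample scale normalisation would destroy the signal and is not
  done.  This is the single most consequential convention in the
  package.
* **Spatial transform.** A small point network (per-point MLP 3→32→64,
  global max, FC 64→32→9) predicts a 3x3 matrix theta applied as
  row-vector x matrix.  The final layer has zero weights and an
  identity bias, so theta starts exactly at the identity; no
  orthogonality regulariser is applied.
* **Location branch.** Two set-abstraction levels (FPS to n/4 then
  n/16; multi-scale ball grouping at two radii per level, fractions
  (0.1, 0.2) and (0.2, 0.4) of the bounding-box diagonal; shared MLPs
  (32,32,64) x2 → 128 channels and (64,64,128) x2 → 256 channels), then
  one shared MLP 256 → 1024 and a global max pool.
* **Feature branch.** Four EdgeConv layers (64, 64, 128, 128), k = 20
  nearest neighbours recomputed in feature space after every layer;
  layer-0 features are the transformed coordinates; edge input is
  (f_i, f_j - f_i).  The concatenated per-point outputs (384 channels)
  are the saliency tap; a shared MLP lifts them to 1024 and a global
  max pools.
* **Head.** concat(1024, 1024) = 2048 → 512 → 128 → 6, outputs ordered
  (BW, CW, HW, BL, CH, HH).  The channel plans are the minimal ones
  consistent with all of the pinned widths (n/16 x 256, 1024 + 1024 →
  2048, 384-wide tap).

**Training.** Loss is the unweighted sum of the six per-metric MSEs on
raw label scales (kg, cm) — the balanced choice for these targets;
optimiser Adam, batch 8, full-scale default lr 1e-3.  The split is by
subject (3:1:1, largest-remainder apportionment for non-divisible
counts) and subject leakage between partitions is a hard error.  The
final head bias is initialised to the training-label mean, so the first
epochs optimise structure rather than climbing from zero to ~211 kg.
Input subsampling to n is redrawn every epoch by default (a light
augmentation; a flag disables it).  The best-validation-loss state is
restored after training.

**Numerical choices at desk scale.**  The networks run on the package's
own float64 reverse-mode autodiff engine.  Two deviations from the
textbook recipe were needed for robust convergence within a
desk-scale optimisation budget (thousands of Adam steps rather than
hundreds of thousands): no BatchNorm (plain affine layers with He init;
keeps the engine small), and leaky rectifiers (slope 0.1) throughout
the regressor — with plain ReLU the max-pool bottleneck can die
irrecoverably early in training for some seeds.  The reduced preset
(`NetConfig.reduced()`: n = 256, quarter widths, k = 10) trains with
lr 3e-3 for the same budget reason.  The segmenter keeps plain ReLU.

## Evaluation metrics

Segmentation: OA, precision, recall, F1, per-class IoU and their mean,
from the binary confusion counts; any 0/0 is reported as undefined
(nan), never silently zero.  Regression: per-metric MSE, RMSE, MAE,
MAPE (percent), and signed per-sample relative error (y - y')/y —
positive means under-prediction.  The mean of the true values is also
computed (it permits an R² if wanted) but drives nothing.  Samples with
zero truth are excluded from MAPE and flagged nan in relative errors.

## Point activation mapping

Per-point saliency for any tapped layers: (1) nearest-neighbour
upsampling aligns each coarse level's features to the n original points
and concatenates them (n x 384 under the default tap — the four
EdgeConv outputs; which layers feed the tap is configurable);
(2) channel-wise max compresses to one value per point; (3) weights
w_i = f_i / (max f - min f).  This normalisation is implemented
literally — the minimum is *not* subtracted, so weights may exceed 1;
`minmax=True` gives the conventional variant.  A zero feature range
falls back to uniform weights with a degenerate flag.  (4) Colours:
after a min-max rescale to ŵ, R = ŵ, B = 1 - ŵ, G = 1 - |2ŵ - 1| —
a blue → green → red ramp; the exact green ramp is a frozen choice, the
hard constraints are only that R rises and B falls with the weight and
the extremes are pure red/blue.

## Scaled-down validation studies

`sowmorph.validation` fixes the two study configurations used by the
acceptance script and test suite, sized for minutes on one CPU:
half-resolution rasters (200 x 120, same field of view), 96 subjects x
5 frames (≈290 training scenes after the subject split) for regression
at the reduced preset (30 epochs), and 50 subjects x 4 frames for
segmentation (6 epochs, 768 points per scene).  Expected outcomes,
asserted by the test suite: held-out MAPE < 10% for every metric and
< 5% for CH and HH (heights map almost directly onto the depth span of
the back cloud, so they are the easiest targets), and held-out
segmentation OA > 95% (the trained model in practice reaches ~99%,
clearly above the ~94% trivial all-background rate of these scenes).

## Determinism

Every stochastic step takes an explicit seed; FPS starts at the
centroid-nearest point and breaks all ties canonically (lexicographic
coordinates, then index), k-NN and ball grouping order ties the same
way, so network outputs are permutation-invariant and runs with the
same seed reproduce bit-identically.

## Known limitations

* The weight proxy is a stand-in law; real BW–shape relations are
  breed- and condition-dependent.
* The deformable-offset loss, kernel count, radii and k values are
  defaults chosen here; none are prescribed by the architecture
  definitions.
* The autodiff engine is single-threaded float64 numpy: fine at
  desk scale, not a route to full-scale (310-epoch, 12,000-frame)
  training.
* Real-scene ingestion is limited to the documented PLY/XYZ/PGM
  formats; no live sensor capture.
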