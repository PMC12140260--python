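# Methods

## The measurement problem

Live fish photographed in water rarely hold a straight posture: the body
curves sideways, so no single camera view contains the true lengths of the
body segments.  `fishmorph` implements a dual-view keypoint morphometry
pipeline for this situation.  Two ideal orthogonal cameras — one lateral
("side"), one dorsal ("top") — share the fish's snout-to-tail direction as
their common horizontal image axis.  Ten side-view landmarks (S1–S10) and
nine top-view landmarks (T1–T9) are placed on anatomically defined points;
four pseudo-landmarks are derived as exact midpoints of annotated pairs:

| derived | parents | meaning |
|---|---|---|
| T10 | fin-left, fin-right | head-end of the top-view body axis |
| S11 | head-up, head-down | head-end of the side-view body axis |
| S12 | small-up, small-down | caudal-peduncle centre |
| T11 | middle-left, middle-right | mid-body point of the top polyline |

## Calibration

Each view is calibrated independently from a ruler of known physical length:
`scale = true_length_cm / pixel_length` (cm per pixel).  Every measurement
multiplies a pixel distance by this per-view scale, which fixes the
direction of the ratio by dimensional analysis.  No lens-distortion or
refraction model is applied; the cameras are treated as orthographic.

## Dual-view 3D length reconstruction

For a segment OA in 3D, let OA′ be its projection into the side (vertical)
plane, α the angle of OA′ to the shared horizontal axis, and β the angle of
the top-plane projection to the same axis.  Then

    |OA| = sqrt( (|OA′| · cos α / cos β)² + (|OA′| · sin α)² )

The horizontal component |OA′|·cos α lies along the shared axis; dividing by
cos β restores the full horizontal-plane length, while the vertical
component |OA′|·sin α is seen undistorted by the side camera.  The formula
is exact for any segment (verified in the tests by a brute-force oracle on
random 3D segments, at 1e−9 relative tolerance), always returns at least
|OA′|, and is guarded for |cos β| < 1e−6, where the segment is viewed nearly
end-on by the top camera and its length is unrecoverable.

Both inclination cosines are used as absolute values: only cos² and sin²
survive in the reconstruction, and the absolute value removes the sign
ambiguity of tailward-pointing vectors.  Projections are likewise magnitudes
because the tail rule compares projections as lengths and takes a minimum.

## The seven traits

All outputs are in cm.  With `dist` in pixels, `ls`/`ts` the side/top scales
and `rec` the reconstruction above:

* **BT** (body thickness) = dist(T2, T3) · ts — planar, top view.
* **BH** (body height) = dist(S3, S4) · ls — planar, side view.
* **THH** (tail-handle height) = dist(S6, S7) · ls — planar, side view.
* **HL** (head length) = rec(dist(S1, S2) · ls, cosα(S1→S2), cosβ(T1→T10)).
* **BL** (body length): the head chord S1→S11 is reconstructed like HL;
  the mid-body side chord length (dist(S11, S12) + dist(S8, S12)) · ls is
  split over the top polyline T10→T11→T7→T8 in proportion to the top-view
  segment lengths, each share reconstructed with the single side chord
  cosine of S12→S11 and its own top segment cosine, and everything summed.
* **FL** (full length) = BL + the tail: both tail-fin tips S9, S10 are
  projected (via tip→S8) onto the body axis S12→S11; the shorter projection
  is reconstructed with the chosen tip's side cosine and the T8→T9 top
  cosine.  An exact tie resolves to S9 deterministically.
* **THW** (tail-handle width) = rec of the summed axis projections of
  S12→S5 and S8→S12, with the S12→S11 side cosine and the T8→T7 top cosine.

The single-chord side cosine for all three mid-body terms (rather than
per-segment side cosines) is deliberate: the procedure models lateral body
curvature through the top view while the side view contributes one overall
inclination.  A per-segment side variant might be more accurate but is a
different method.

Specimens with missing landmarks are rejected before measurement (every
formula consumes specific named points; there is no defined behaviour for
occlusion).  Head-right annotations are mirrored to the canonical head-left
orientation on load, with a logged warning.

## Error metrics

Automated values `el` are scored against manual references `ml` per trait:
RMSE = sqrt(mean (el−ml)²), MAE = mean |el−ml|, MRE = mean |el−ml|/ml.  The
across-trait "average" is the unweighted mean of the seven per-trait values.
The bundled 20-fish channel-catfish study (total length 12–17 cm, seven
traits measured both ways) is shipped as packaged CSV with a SHA-256 check
and is reproduced cell-for-cell by the test suite at the printed precision.

## Synthetic specimens

The generator builds a piecewise-linear 3D centerline — head, three
mid-body segments, tail — with per-joint bend angles confined to the
horizontal plane by default (resting fish curve sideways; a pitch profile
exists behind a parameter for robustness studies).  Landmark pairs are
placed symmetrically about the centerline: height pairs vertically, width
pairs laterally, tail-fin tips behind the body/tail junction with a vertical
fork and deliberately distinct longitudinal setbacks (a perfectly symmetric
fork would make the two tail projections an exact tie, a knife-edge where
floating-point rounding, not geometry, would pick the tip).

Default dimensions emulate the 12–17 cm size class of the bundled study:
head 3.0 cm, mid segments 2.5/3.0/3.0 cm, tail 2.8 cm, body height 2.3 cm,
thickness 2.1 cm, peduncle height 1.5 cm; random draws sample uniformly
around these (segment lengths ±~20%, cumulative yaw within ±30° so the body
never doubles back on the axis, pose offset ±1 cm).

**Ground truth is defined by the measurement decomposition applied to the
exact 3D coordinates** (an independent numpy code path on cm coordinates:
side plane = axial/vertical, top plane = axial/lateral; no pixels, no
calibration).  This choice makes the noiseless round trip
generate → project → measure an exact oracle for the *implementation*: any
discrepancy is a code defect, not the procedure's own approximation error.
For straight fish the decomposition equals the centerline chain length,
which a test asserts separately.  Consequences to keep in mind: passing
round-trip tests demonstrate implementation correctness, not the biological
accuracy of the chord-plus-proportion approximation on real fish, and the
rasterized silhouettes are flat-shaded polygons over uniform noise — no
texture, refraction, lighting or occlusion, so detector results on them say
nothing about real-image accuracy.

Annotation noise is modelled as i.i.d. Gaussian jitter per keypoint
coordinate; a test checks the measurement error grows monotonically with
the jitter scale, and another checks the mean displacement matches the
folded-normal expectation σ·sqrt(π/2).

## Keypoint detector

A stacked-hourglass heatmap network implemented directly over numpy with a
small reverse-mode autodiff core (convolution via im2col, ReLU, 2×2 max
pooling, 2× nearest-neighbour upsampling).  Two fourth-order hourglass
modules are stacked with intermediate supervision; the loss is the heatmap
MSE summed over stacks; optimization is Adam at learning rate 1e−3.

Numerical choices that matter:

* **Zero-initialized residual branches.**  The second convolution of every
  residual block starts at zero, so the unnormalized network begins as the
  identity.  Without this the stacked branches compound activation variance
  (~36× at order 4) and early optimization is erratic and seed-sensitive.
* **Near-zero heads.**  The 1×1 heatmap heads start at scale 1e−3, so the
  initial loss equals the target heatmap energy.
* **Desk-scale sizes.**  64×64 inputs, 16×16 heatmaps (upscale factor 4),
  16 channels, Gaussian bump σ = 2 heatmap px, ~300 full-batch Adam steps
  with a 0.3× learning-rate drop at 70% of training.  σ = 2 spreads the
  gradient signal of thin structures (the mouth wedge) far enough to
  localize them; σ = 1 leaves systematic multi-cell errors at such points.
  These sizes are the package's own training recipe for a single CPU; the
  full-resolution regime (2448×2048 inputs, 512×512 or 128×128 maps
  upscaled ×16) is expressible in the same configuration but is not the
  tested regime.
* **Decoding** is the per-map argmax times the upscale factor, without
  sub-pixel refinement, so the quantization error is bounded by one heatmap
  cell per axis.  Ties resolve to the lowest row-major index; an all-zero
  map decodes to the map centre with a warning.  Rectangular images are
  letterboxed with a recorded transform.

Two independent models are trained, one per view (10 vs 9 keypoints).
Checkpoints are `.npz` archives of the parameter arrays plus the JSON
config.

## Problem sizes and determinism

The test suite and the acceptance script use: 1000 random segments for the
reconstruction oracle, 100 random specimens for noiseless recovery, 20
rasterized 64×64 side views and 300 training steps for the detector run,
and the bundled 20-fish table for the metric regression.  Every stochastic
component takes an explicit seed (numpy `default_rng`; no global state);
training itself is deterministic given the dataset and initialization.

## Known limitations

* No perspective, lens distortion, or water-refraction modelling; the
  ruler's placement depth relative to the fish is assumed equivalent.
* Partial annotations are rejected, not imputed.
* The label set is fixed to this two-view skeleton; other species or
  skeletons would need a new label table and formula set.
* The detector's accuracy on real photographs is out of scope: training
  and evaluation here use synthetic silhouettes only.
* T4 (fin-up) is carried in the data model but consumed by no formula.
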