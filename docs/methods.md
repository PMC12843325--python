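# Methods

## The representation

A gait skeleton image is a fixed-size grayscale template summarizing a 3D
skeletal walking sequence.  Per frame the 17-keypoint skeleton is drawn as
a binary image — either the 16 bones as capsules (stadium footprints) of
thickness *t* pixels, or the 17 joints as discs of radius *r* pixels — and
the template is the pixel-wise arithmetic mean of those frames over the
detected gait cycles.  Values therefore read as occupancy frequency in
[0, 1], exactly analogous to a silhouette energy image; a max-accumulation
variant is available behind `RunConfig(accumulate="max")` but the mean is
the default and the tested path.  Rasterization is a hard geometric
membership test (pixel center within distance *t*/2 of the bone segment,
or within *r* of a joint) with no anti-aliasing, so rendered output is
bit-reproducible and exactly equals a brute-force per-pixel distance
evaluation; the production code only restricts the test to each
footprint's bounding box.  Edges with an endpoint of confidence 0 are
skipped, never extrapolated.

## Body model and layout conversion

The 17-keypoint model keeps the axial chain (head, neck, shoulder center,
spine center, hip center) and the limb chains to wrists and ankles; hands,
feet and facial landmarks are dropped as the least reliably tracked and
least gait-informative.  The 16 bones form a tree with no direct
left–right limb link.  Kinect-v2 input maps keypoint-for-keypoint (with z
negated, since Kinect's z points away from the camera while the package
convention is x right, y up, z toward the camera).  MediaPipe input maps
limb landmarks directly and synthesizes the four central-axis keypoints as
unweighted midpoints: shoulder center and hip center from the bilateral
pairs, spine center from those two, and — since MediaPipe has no neck
landmark — neck as the midpoint of head (nose) and shoulder center, a
package convention.  MediaPipe world landmarks are assumed already
expressed in the package axis convention.  Midpoint confidence is the
minimum of the contributing confidences.  All rules ship as a YAML data
file (`gsigait/data/mappings.yaml`) and the converters are table-driven.

## View normalization

`M_view = Rz(θz) · S · Ry(θy) · T` in homogeneous coordinates:

* **T** translates the sequence-mean hip center to the origin.  The mean
  (rather than first-frame or per-frame) anchor makes the transform a
  single rigid map of the whole sequence; per-frame anchoring is deferred
  to the trajectory-removal step.
* **θy** comes from a total-least-squares (principal-axis) fit of the
  hip-center trajectory in the horizontal XZ plane — robust to pose noise
  on individual joints — wrapped into [−π/2, π/2) so the walking *axis* is
  rotated onto X without turning the subject's back to the viewer.
* **S** = diag(−1, 1, 1, 1) is applied exactly when the oriented walking
  direction still points toward −X after Ry, so left-to-right and
  right-to-left passes of the same walker produce identical templates
  (mirror consistency).
* **θz** verticalizes the sequence-mean torso axis (hip center → shoulder
  center) in the XY plane.  Using the mean over all frames rather than a
  per-frame angle avoids injecting frame-rate jitter into the template.

A stationary subject (total hip displacement under 1 cm) has no walking
direction and raises a degenerate-trajectory error.

Translation stabilization then subtracts each frame's hip-center X and Z
from all joints of that frame, leaving Y untouched so the vertical gait
oscillation — part of the signature — survives.

## Projection and canvas fit

Orthographic projection drops Z.  One global bounding box over all valid
joints of all frames sets a single uniform scale such that the box height
equals 90% of the 120-pixel canvas height (the 10% margin keeps thick
strokes from clipping; both the canvas size and margin are `RunConfig`
constants).  The box is centered and Y is flipped into image coordinates
(origin top-left, v downward, pixel centers at integer + 0.5).  One scale
per sequence keeps limb excursion comparable across frames; it also means
the template preserves within-sequence proportions only — whether
between-subject body size should survive normalization is a protocol
choice this package does not take a position on.

## Gait-cycle segmentation

The horizontal ankle separation |u_L − u_R| peaks twice per stride, so
stride boundaries are every second local maximum of the mean-subtracted,
moving-average-smoothed signal (window ⌈fps/10⌉ frames; peaks at least
0.2 s apart).  With fewer than two maxima the whole sequence becomes one
cycle with a logged warning, so no sequence is ever rejected.  The default
builds one template from all frames spanned by the detected cycles; a
per-cycle option (`compute_gsi_per_cycle`) exists.  Ankle-separation
extrema are the standard choice in template-based gait work and are
computable from the 17-keypoint set alone.

## Synthetic gait

The simulator emulates a lateral-corridor acquisition: per-subject limb
lengths, stride frequency (cadence, 0.8–1.2 Hz), hip/knee/arm swing
amplitudes and vertical bounce are drawn once per subject from fixed
uniform ranges; trials of the same subject differ by starting phase, a 1%
jitter on cadence and amplitudes, and i.i.d. Gaussian joint noise (default
σ = 5 mm, a typical depth-sensor tracking error).  Covariates are modeled
as their dominant effect on pose estimates: a carried bag suppresses arm
swing on one side (remaining fraction ≤ 0.3); a coat biases trunk and hip
keypoints outward by 1–3 cm and adds 5 mm of joint noise.  These
perturbation models are package inventions calibrated only to produce the
qualitative ordering (coat harder than bag); they do not claim
biomechanical fidelity — no double-support timing, ground-reaction forces
or soft-tissue simulation — so passing tests demonstrate pipeline
correctness and identity recoverability under this generative model, not
performance on real recordings.  Matching silhouettes for the energy-image
baseline are the normalized skeleton drawn as capsules of a given body
width (at zero width this coincides with a 1-pixel line rendering).
Randomness derives from one seed through `SeedSequence` spawn keys
(subject index; subject, trial, view, condition), so cohorts are
bit-reproducible.

## Recognition harness

The classifier is the classic two-block template CNN: conv 18@7×7 →
batch-norm → ReLU → 2×2 max-pool → conv 45@5×5 → batch-norm → ReLU → pool
→ fully connected 1024 → ReLU → dropout 0.5 → linear softmax.  Batch-norm
and dropout are the only departures from the original design, added for
optimization stability on small cohorts.  The implementation is NumPy
(im2col convolution with hand-derived backprop, `gsigait/nn.py`), written
as part of the package so the harness has no deep-learning framework
dependency; it is deterministic given the seed.

Two protocols:

* **Leave-one-trial-out** (closed set): trials 01–08 train (the last
  training trial per subject is the early-stopping validation split),
  09–10 test; AdamW, lr 1e-3, weight decay 1e-4, cosine schedule with a
  5-epoch warm-up, early stopping patience 10, batch 32, max 50 epochs.
* **Gallery/probe** (unseen identities): the network is trained with
  cross-entropy/Adam on a disjoint subject set, then each probe template
  is assigned the identity of the nearest gallery template by cosine
  distance in the 1024-d penultimate (post-ReLU, pre-dropout) embedding —
  the standard matching rule in this architecture's lineage, needed
  because a softmax over training identities cannot classify subjects it
  never saw.  Ties break to the lowest gallery index.

The same `TrainConfig` is reused verbatim across line-based, joint-based
and silhouette-energy inputs so performance differences are attributable
to the representation.  Rank-1 matrices are tabulated per (gallery view,
probe view, covariate); `summarize_matrix` and `covariate_report` always
recompute means from the matrix entries, rounding only at output — the
published joint-template benchmark table's printed 90° column mean (30.01)
disagrees with its own entries (which average 31.43), and its printed
same-view mean (74.8) with the diagonal entries (74.74); this package
reports recomputed values and treats the printed column means as separate
inputs where an aggregation of printed values is wanted.

## Problem sizes and numerical choices

The reference synthetic cohort is 10 subjects × 10 trials of 4 s at
30 fps, lateral view, σ = 5 mm — large enough that identity is recoverable
(leave-one-out nearest-neighbor rank-1 ≥ 95% on flattened joint templates)
while a full CNN leave-one-trial-out run completes in minutes on one core.
Geometric assertions use 1e-9 tolerances (rigid-transform isometry,
rotation recovery), mirror consistency 1e-6 (two independent
normalization paths), template round-trips 1/255 (8-bit PNG
quantization).  Degenerate inputs: stationary subjects and zero-height
bounding boxes raise errors; missing joints (confidence 0) are carried as
(0, 0, 0) sentinels, excluded from bounding boxes, direction fits and
rendering.

## Known limitations

* Orthographic (not pinhole) projection; no camera intrinsics.
* No temporal smoothing of joints; noisy input passes straight through to
  the templates.
* The simulator's planar-dominant kinematics have no out-of-plane leg
  motion, so cross-view normalization is exactly invertible there —
  real sequences will show residual view effects.
* Cross-view *training* (multi-view galleries, view-transfer models) is
  not implemented; the harness evaluates cross-view matching only.
* Dataset archive loaders for real benchmarks are out of scope; input is
  the documented JSON-lines skeleton format.
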