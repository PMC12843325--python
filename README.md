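# gsigait

Skeleton-based gait recognition with compact 2D motion templates.

Silhouette templates such as the Gait Energy Image (GEI) — the pixel-wise
mean of size-normalized binary silhouettes over a gait cycle — are strong
biometric descriptors under controlled conditions but degrade when
appearance changes (clothing, carried objects, viewpoint).  `gsigait`
implements the skeletal counterpart: **Gait Skeleton Images (GSI)**, which
encode a 3D joint-trajectory sequence as a fixed-size grayscale template by

1. converting heterogeneous pose sources (Kinect-v2 25 joints, MediaPipe 33
   landmarks) to a unified 17-keypoint kinematic tree,
2. rigidly aligning the sequence to a canonical lateral view with the
   homogeneous factorization `M_view = Rz(θz) · S · Ry(θy) · T`
   (translation of the mean hip center to the origin, rotation of the
   walking axis onto X, conditional reflection so the subject always faces
   +X, residual torso-tilt correction),
3. removing the horizontal walking trajectory per frame while preserving
   vertical gait oscillation,
4. orthographically projecting onto an 80×120 pixel canvas, and
5. rasterizing each frame — bones as capsules of thickness *t* (GSI-Lines)
   or joints as discs of radius *r* (GSI-Joints) — and averaging the binary
   frames over the detected gait cycles:  `GSI(x,y) = (1/N) Σ_t B_t(x,y)`.

The package also provides the GEI baseline, a two-block CNN recognition
harness (18×7×7 and 45×5×5 convolutions with batch-norm and dropout,
1024-d embedding) with leave-one-trial-out and gallery/probe protocols,
rank-1 cross-view and covariate reporting, and a parametric gait simulator
that generates labeled cohorts with per-subject kinematics, camera
viewpoint, and bag/coat covariates — so the entire pipeline is testable
without external datasets.

Intended users: researchers in vision-based gait biometrics and movement
analysis who want an inspectable, deterministic skeletal-template pipeline
or a controlled synthetic benchmark for template-based methods.

## Worked example

```python
import numpy as np
from gsigait import RunConfig, TrainConfig, compute_gsi
from gsigait.simulate import GaitParams, CovariateSpec, simulate_sequence, make_cohort
from gsigait.recognition import render_templates, run_loto

# one noise-free walker, two camera viewpoints
cfg = RunConfig(variant="joints", radius_px=8)
p = GaitParams()
t0  = compute_gsi(simulate_sequence(p, CovariateSpec(view_deg=0.0),  4.0, 30.0, 0.0, 0), cfg)
t90 = compute_gsi(simulate_sequence(p, CovariateSpec(view_deg=90.0), 4.0, 30.0, 0.0, 0), cfg)
print("mean abs template difference, 0° vs 90°:", np.abs(t0.pixels - t90.pixels).mean())

# 10-subject cohort, leave-one-trial-out CNN recognition
manifest = make_cohort(10, 10, views=(90.0,), covariates=("NM",), seed=1, noise_sigma=0.005)
rendered = render_templates(manifest, cfg)
model, log, acc = run_loto(rendered, TrainConfig(protocol="loto"), seed=1)
print(f"held-out accuracy: {acc:.1f}% after {len(log)} epochs")
```

Output:

```
mean abs template difference, 0° vs 90°: 0.0
held-out accuracy: 100.0% after 17 epochs
```

The zero difference shows the view normalization exactly undoing a rigid
90° camera rotation of a noise-free walk; the held-out accuracy shows that
the per-subject kinematic parameters drawn by the simulator are recoverable
from the joint-based templates by the CNN (trials 01–08 train, 09–10 test).

A command-line interface mirrors the library:
`gsi simulate`, `gsi render`, `gsi sweep`, `gsi train`, `gsi eval`
(see `gsi --help`).

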