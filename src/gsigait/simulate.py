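"""Parametric gait simulator: labeled 3D walking sequences with
controllable identity, viewpoint and covariate structure.

The walker is a planar-dominant kinematic chain: the hip center advances
along +X at constant speed with a vertical bounce at twice the stride
frequency; thighs and shanks follow sinusoidal hip/knee angles with the
two legs in antiphase; arms swing in antiphase with the ipsilateral leg.
Identity lives in the per-subject limb lengths, cadence and amplitudes,
drawn once per subject from fixed uniform ranges.  Covariates perturb the
chain the way carried bags and coats perturb real pose estimates: a bag
suppresses arm swing on one side; a coat thickens the torso (outward bias
of trunk/hip keypoints up to 3 cm) and raises joint noise.  The camera
viewpoint is a rigid yaw rotation of the finished sequence.

All randomness flows from one integer seed through documented
``SeedSequence`` splits keyed by subject and trial, so any cohort is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import Layout, SequenceMeta, SkeletonSequence, SilhouetteStack, write_sequence
from .geometry import normalize_sequence, project_and_fit
from .templates import _stamp_capsule
from .topology import GSI17_EDGES, GSI17_INDEX

__all__ = [
    "GaitParams",
    "CovariateSpec",
    "simulate_sequence",
    "simulate_silhouettes",
    "make_cohort",
    "subject_params",
]

_K = GSI17_INDEX

# per-subject uniform draw ranges (meters, Hz, radians)
_PARAM_RANGES = {
    "thigh": (0.38, 0.46),
    "shank": (0.39, 0.47),
    "upper_arm": (0.28, 0.34),
    "forearm": (0.24, 0.30),
    "torso": (0.45, 0.55),
    "neck_head": (0.22, 0.28),
    "shoulder_width": (0.34, 0.42),
    "hip_width": (0.28, 0.36),
    "cadence": (0.8, 1.2),
    "hip_amp": (0.30, 0.45),
    "knee_amp": (0.60, 1.00),
    "arm_amp": (0.25, 0.45),
    "bounce": (0.015, 0.035),
}


@dataclass
class GaitParams:
    """Kinematic identity of one walker.  Lengths in meters, cadence is the
    stride (full-cycle) frequency in Hz, amplitudes in radians, bounce in
    meters.  Left and right legs are locked in antiphase (offset pi)."""

    thigh: float = 0.42
    shank: float = 0.43
    upper_arm: float = 0.31
    forearm: float = 0.27
    torso: float = 0.50
    neck_head: float = 0.25
    shoulder_width: float = 0.38
    hip_width: float = 0.32
    cadence: float = 1.0
    hip_amp: float = 0.38
    knee_amp: float = 0.80
    arm_amp: float = 0.35
    bounce: float = 0.025
    phase0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("thigh", "shank", "upper_arm", "forearm", "torso", "neck_head"):
            v = getattr(self, name)
            if not (0.1 <= v <= 0.8):
                raise ValueError(f"{name}={v} outside [0.1, 0.8] m")
        if not (0.6 <= self.cadence <= 1.4):
            raise ValueError(f"cadence={self.cadence} outside [0.6, 1.4] Hz")
        for name in ("hip_amp", "knee_amp", "arm_amp", "bounce"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CovariateSpec:
    """Acquisition condition: NM (normal), BG (bag: one-sided arm-swing
    suppression), CL (coat: outward trunk-keypoint bias and extra joint
    noise), plus the camera yaw in degrees."""

    condition: str = "NM"
    view_deg: float = 0.0
    bag_side: str = "l"  # arm whose swing the bag suppresses
    bag_swing_factor: float = 0.15  # remaining fraction of arm swing, in [0, 0.3]
    coat_bias_m: float = 0.02  # outward trunk/hip bias, up to 0.03
    coat_extra_sigma: float = 0.005  # added joint noise under CL, meters

    def __post_init__(self) -> None:
        if self.condition not in ("NM", "BG", "CL"):
            raise ValueError("condition must be NM, BG or CL")
        if not (0.0 <= self.view_deg < 360.0):
            raise ValueError("view_deg must be in [0, 360)")
        if not (0.0 <= self.bag_swing_factor <= 0.3):
            raise ValueError("bag_swing_factor must be in [0, 0.3]")
        if not (0.0 <= self.coat_bias_m <= 0.03):
            raise ValueError("coat_bias_m must be in [0, 0.03]")
        if self.bag_side not in ("l", "r"):
            raise ValueError("bag_side must be 'l' or 'r'")


def subject_params(seed: int, subject_index: int) -> GaitParams:
    """Deterministic per-subject parameter draw from the stated ranges."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject_index,)))
    vals = {name: rng.uniform(lo, hi) for name, (lo, hi) in _PARAM_RANGES.items()}
    return GaitParams(**vals)


def _gsi17_frames(params: GaitParams, cov: CovariateSpec, t: np.ndarray) -> np.ndarray:
    p = params
    n = t.shape[0]
    phi = 2 * np.pi * p.cadence * t + p.phase0
    out = np.zeros((n, 17, 3))

    leg = p.thigh + p.shank
    stride_len = 2.0 * leg * np.sin(p.hip_amp)
    speed = stride_len * p.cadence

    hip_c = np.stack(
        [speed * t, leg + p.bounce * np.sin(2 * phi), np.zeros(n)], axis=1
    )
    out[:, _K["hip_center"]] = hip_c
    out[:, _K["spine_center"]] = hip_c + np.array([0, p.torso / 2, 0])
    sh_c = hip_c + np.array([0, p.torso, 0])
    out[:, _K["shoulder_center"]] = sh_c
    out[:, _K["neck"]] = sh_c + np.array([0, 0.35 * p.neck_head, 0])
    out[:, _K["head"]] = sh_c + np.array([0, p.neck_head, 0])

    arm_amp = {"l": p.arm_amp, "r": p.arm_amp}
    if cov.condition == "BG":
        arm_amp[cov.bag_side] = p.arm_amp * cov.bag_swing_factor

    for side, sgn, leg_phase in (("l", +1.0, 0.0), ("r", -1.0, np.pi)):
        ph = phi + leg_phase
        hip = hip_c + np.array([0, -0.02, 0]) + sgn * np.array([0, 0, p.hip_width / 2])
        out[:, _K[f"{side}_hip"]] = hip
        th = p.hip_amp * np.sin(ph)
        knee = hip + p.thigh * np.stack([np.sin(th), -np.cos(th), np.zeros(n)], axis=1)
        out[:, _K[f"{side}_knee"]] = knee
        kf = p.knee_amp * (1 - np.cos(ph - 0.4 * np.pi)) / 2  # flexes once per stride
        ts = th - kf
        out[:, _K[f"{side}_ankle"]] = knee + p.shank * np.stack(
            [np.sin(ts), -np.cos(ts), np.zeros(n)], axis=1
        )

        sh = sh_c + np.array([0, -0.02, 0]) + sgn * np.array([0, 0, p.shoulder_width / 2])
        out[:, _K[f"{side}_shoulder"]] = sh
        ta = arm_amp[side] * np.sin(ph + np.pi)  # antiphase with ipsilateral leg
        elbow = sh + p.upper_arm * np.stack([np.sin(ta), -np.cos(ta), np.zeros(n)], axis=1)
        out[:, _K[f"{side}_elbow"]] = elbow
        tf = ta + 0.35  # constant elbow flexion keeps the forearm length fixed
        out[:, _K[f"{side}_wrist"]] = elbow + p.forearm * np.stack(
            [np.sin(tf), -np.cos(tf), np.zeros(n)], axis=1
        )

    if cov.condition == "CL":
        b = cov.coat_bias_m
        out[:, _K["l_hip"], 2] += b
        out[:, _K["r_hip"], 2] -= b
        out[:, _K["l_shoulder"], 2] += b
        out[:, _K["r_shoulder"], 2] -= b
        out[:, _K["hip_center"], 0] += b / 2
        out[:, _K["spine_center"], 0] += b / 2
        out[:, _K["shoulder_center"], 0] += b / 2
    return out


def _to_kinect25(frames17: np.ndarray) -> np.ndarray:
    """Extrapolate the extremity joints and reorder into the Kinect-v2
    25-joint layout (camera frame with z away from the camera)."""

    def unit(v):
        return v / np.linalg.norm(v, axis=-1, keepdims=True)

    g = {name: frames17[:, i] for name, i in _K.items()}
    n = frames17.shape[0]
    k = np.zeros((n, 25, 3))
    order = {
        0: "hip_center", 1: "spine_center", 2: "neck", 3: "head",
        4: "l_shoulder", 5: "l_elbow", 6: "l_wrist",
        8: "r_shoulder", 9: "r_elbow", 10: "r_wrist",
        12: "l_hip", 13: "l_knee", 14: "l_ankle",
        16: "r_hip", 17: "r_knee", 18: "r_ankle",
        20: "shoulder_center",
    }
    for idx, name in order.items():
        k[:, idx] = g[name]
    for side, hand, tip, thumb, foot, wrist, elbow, ankle, knee in (
        ("l", 7, 21, 22, 15, "l_wrist", "l_elbow", "l_ankle", "l_knee"),
        ("r", 11, 23, 24, 19, "r_wrist", "r_elbow", "r_ankle", "r_knee"),
    ):
        wdir = unit(g[wrist] - g[elbow])
        k[:, hand] = g[wrist] + 0.08 * wdir
        k[:, tip] = g[wrist] + 0.15 * wdir
        k[:, thumb] = g[wrist] + 0.05 * wdir + np.array([0, 0, 0.02 if side == "l" else -0.02])
        adir = unit(g[ankle] - g[knee])
        # foot points forward from the ankle, orthogonal-ish to the shank
        k[:, foot] = g[ankle] + np.array([0.13, -0.04, 0.0]) + 0.0 * adir
    # package convention z-toward-camera -> Kinect z-away
    return k * np.array([1.0, 1.0, -1.0])


def simulate_sequence(
    params: GaitParams,
    cov: CovariateSpec = None,
    duration: float = 4.0,
    fps: float = 30.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    layout: Layout = Layout.GSI17,
    meta: Optional[SequenceMeta] = None,
) -> SkeletonSequence:
    """Generate one walking sequence.

    Stages: kinematic chain (with any BG arm-swing suppression) -> CL
    keypoint bias -> i.i.d. Gaussian joint noise (sigma plus any CL extra)
    -> rigid yaw rotation to the camera viewpoint -> optional re-layout as
    Kinect-v2 25 joints (extremities extrapolated) to exercise converters.
    """
    cov = cov or CovariateSpec()
    n = int(round(duration * fps))
    if n < 2:
        raise ValueError("duration * fps must give at least 2 frames")
    t = np.arange(n) / fps
    frames = _gsi17_frames(params, cov, t)

    sigma = noise_sigma + (cov.coat_extra_sigma if cov.condition == "CL" else 0.0)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, sigma, size=frames.shape)

    if cov.view_deg != 0.0:
        th = np.deg2rad(cov.view_deg)
        c, s = np.cos(th), np.sin(th)
        R = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        frames = frames @ R.T

    if layout is Layout.KINECT25:
        frames = _to_kinect25(frames)
    elif layout is not Layout.GSI17:
        raise ValueError("simulator emits GSI17 or KINECT25 layouts")

    m = meta or SequenceMeta()
    if m.view_deg is None:
        m = dataclasses.replace(m, view_deg=cov.view_deg)
    if m.covariate is None:
        m = dataclasses.replace(m, covariate=cov.condition)
    return SkeletonSequence(layout=layout, frames=frames, fps=fps, meta=m)


def simulate_silhouettes(seq: SkeletonSequence, body_width: float = 0.10) -> SilhouetteStack:
    """Matching binary silhouettes: the normalized, canvas-fitted skeleton
    drawn as a union of capsules whose pixel radius is 0.5 plus half the
    body width in pixels — at zero body width this coincides with a
    1-pixel-thick line rendering."""
    from .topology import to_gsi17

    g = normalize_sequence(to_gsi17(seq))
    proj = project_and_fit(g)
    radius = 0.5 + proj.scale * body_width / 2.0
    frames = []
    for i in range(proj.frames.shape[0]):
        img = np.zeros((proj.canvas_h, proj.canvas_w), dtype=bool)
        for a, b in GSI17_EDGES:
            if proj.confidence[i, a] <= 0 or proj.confidence[i, b] <= 0:
                continue
            _stamp_capsule(img, proj.frames[i, a], proj.frames[i, b], radius)
        frames.append(img.astype(np.uint8))
    return SilhouetteStack(frames=np.stack(frames), fps=seq.fps, meta=seq.meta)


_COV_CODE = {"NM": 0, "BG": 1, "CL": 2}


def make_cohort(
    n_subjects: int,
    trials_per_subject: int,
    views: Sequence[float] = (90.0,),
    covariates: Sequence[str] = ("NM",),
    seed: int = 0,
    duration: float = 4.0,
    fps: float = 30.0,
    noise_sigma: float = 0.005,
    layout: Layout = Layout.GSI17,
    out_dir: Optional[str] = None,
) -> pd.DataFrame:
    """Generate a labeled cohort and its manifest.

    Per-subject kinematics are drawn once from the stated uniform ranges
    (keyed by (seed, subject)); each trial adds a random gait phase and a
    small (1%) jitter on cadence and amplitudes, far below the
    between-subject parameter spread.  Returns a manifest DataFrame with
    columns subject, trial, view_deg, covariate and either an in-memory
    ``sequence`` column or, when ``out_dir`` is given, a ``path`` column of
    written JSON-lines files.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    rows = []
    for si in range(1, n_subjects + 1):
        base = subject_params(seed, si)
        for trial in range(1, trials_per_subject + 1):
            for view in views:
                for condition in covariates:
                    key = (si, trial, int(round(view)) % 360, _COV_CODE[condition])
                    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))
                    jit = lambda v: v * (1.0 + rng.normal(0.0, 0.01))
                    params = dataclasses.replace(
                        base,
                        cadence=float(np.clip(jit(base.cadence), 0.6, 1.4)),
                        hip_amp=jit(base.hip_amp),
                        knee_amp=jit(base.knee_amp),
                        arm_amp=jit(base.arm_amp),
                        phase0=float(rng.uniform(0, 2 * np.pi)),
                    )
                    cov = CovariateSpec(
                        condition=condition,
                        view_deg=float(view),
                        bag_side="l" if rng.integers(2) == 0 else "r",
                        coat_bias_m=float(rng.uniform(0.01, 0.03)),
                    )
                    noise_seed = int(rng.integers(2**31 - 1))
                    meta = SequenceMeta(
                        subject=f"S{si:03d}",
                        trial=f"{trial:02d}",
                        view_deg=float(view),
                        covariate=condition,
                    )
                    seq = simulate_sequence(
                        params, cov, duration, fps, noise_sigma, noise_seed, layout, meta
                    )
                    row = {
                        "subject": meta.subject,
                        "trial": meta.trial,
                        "view_deg": float(view),
                        "covariate": condition,
                        "params": params,
                    }
                    if out_dir is None:
                        row["sequence"] = seq
                    else:
                        d = Path(out_dir)
                        d.mkdir(parents=True, exist_ok=True)
                        p = d / f"{meta.subject}_t{meta.trial}_v{int(round(view)):03d}_{condition}.jsonl"
                        write_sequence(seq, p)
                        row["path"] = str(p)
                    rows.append(row)
    return pd.DataFrame(rows)
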