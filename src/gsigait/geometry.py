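"""Rigid view normalization, translation stabilization and 2D projection.

A sequence is aligned to a canonical lateral orientation by a single
homogeneous matrix

    M_view = Rz(theta_z) @ S @ Ry(theta_y) @ T

where T translates the sequence-mean hip center to the origin, Ry(theta_y)
rotates the walking axis into the X axis, S = diag(-1, 1, 1, 1) reflects
sequences that walk toward -X so every subject faces +X with the same body
side toward the viewer, and Rz(theta_z) removes residual in-plane torso
tilt.  Because the product is rigid (up to the reflection), all pairwise
joint distances are preserved.

After view normalization the global trajectory is removed per frame
(horizontal components only, so vertical gait oscillation survives), depth
is dropped by orthographic projection, and the sequence is fitted to a
fixed 80x120 pixel canvas with one global scale so limb excursion stays
comparable across frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Layout, SkeletonSequence
from .topology import GSI17_INDEX

__all__ = [
    "DegenerateTrajectoryError",
    "ViewTransform",
    "ProjectedSequence",
    "estimate_walking_direction",
    "build_view_transform",
    "apply_view_transform",
    "normalize_translation",
    "project_and_fit",
]

_HIP = GSI17_INDEX["hip_center"]
_SHOULDER_C = GSI17_INDEX["shoulder_center"]

MIN_DISPLACEMENT_M = 0.01  # below 1 cm of total hip travel the subject is stationary


class DegenerateTrajectoryError(ValueError):
    """Hip trajectory too short (or bounding box empty) to normalize."""


def _translation(offset: np.ndarray) -> np.ndarray:
    M = np.eye(4)
    M[:3, 3] = offset
    return M


def _rot_y(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    M = np.eye(4)
    M[0, 0], M[0, 2] = c, s
    M[2, 0], M[2, 2] = -s, c
    return M


def _rot_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    M = np.eye(4)
    M[0, 0], M[0, 1] = c, -s
    M[1, 0], M[1, 1] = s, c
    return M


@dataclass
class ViewTransform:
    """Factored view-normalization matrix and its parameters."""

    T: np.ndarray  # 4x4 translation (mean hip center -> origin)
    theta_y: float  # rotation about Y aligning the walking axis with X
    reflect: bool  # whether S = diag(-1,1,1,1) is applied
    theta_z: float  # residual in-plane tilt correction

    @property
    def S(self) -> np.ndarray:
        return np.diag([-1.0, 1.0, 1.0, 1.0]) if self.reflect else np.eye(4)

    @property
    def M_view(self) -> np.ndarray:
        return _rot_z(self.theta_z) @ self.S @ _rot_y(self.theta_y) @ self.T


@dataclass
class ProjectedSequence:
    """Per-frame 2D keypoints in canvas pixel coordinates.

    ``frames`` has shape (n, 17, 2) holding (u, v): u grows rightward,
    v downward, origin at the canvas top-left, pixel centers at
    integer + 0.5.  ``scale`` is pixels per meter; ``offsets`` the (u, v)
    shift applied after scaling.
    """

    frames: np.ndarray
    confidence: np.ndarray
    canvas_w: int
    canvas_h: int
    scale: float
    offsets: tuple
    fps: float
    meta: object = None


def _valid_hip_frames(seq: SkeletonSequence) -> np.ndarray:
    return seq.confidence[:, _HIP] > 0


def estimate_walking_direction(seq: SkeletonSequence) -> np.ndarray:
    """Horizontal unit vector of the hip-center trajectory.

    Total-least-squares (principal axis) fit of the hip-center positions in
    the horizontal XZ plane, oriented from the first toward the last frame.
    Raises :class:`DegenerateTrajectoryError` when total hip displacement
    is below 1 cm.
    """
    if seq.layout is not Layout.GSI17:
        raise ValueError("walking direction needs a GSI17 sequence")
    ok = _valid_hip_frames(seq)
    if ok.sum() < 2:
        raise DegenerateTrajectoryError("need at least 2 frames with a valid hip center")
    hips = seq.frames[ok][:, _HIP, :]
    xz = hips[:, [0, 2]]
    disp = xz[-1] - xz[0]
    if np.linalg.norm(disp) < MIN_DISPLACEMENT_M:
        raise DegenerateTrajectoryError(
            f"hip displacement {np.linalg.norm(disp) * 100:.2f} cm < 1 cm: stationary subject"
        )
    centered = xz - xz.mean(axis=0)
    # principal axis of the 2x2 scatter = TLS line direction
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis @ disp < 0:  # orient first -> last
        axis = -axis
    axis = axis / np.linalg.norm(axis)
    return np.array([axis[0], 0.0, axis[1]])


def build_view_transform(seq: SkeletonSequence) -> ViewTransform:
    """Estimate the canonical-view normalization for a GSI17 sequence.

    theta_y is chosen in [-pi/2, pi/2) so that the undirected walking axis
    maps onto the X axis; the reflection S is triggered exactly when the
    oriented walking direction then points toward -X.  theta_z verticalizes
    the sequence-mean torso axis (hip center -> shoulder center), computed
    over all frames to avoid frame-rate jitter.
    """
    d = estimate_walking_direction(seq)
    ok = _valid_hip_frames(seq)
    mean_hip = seq.frames[ok][:, _HIP, :].mean(axis=0)
    T = _translation(-mean_hip)

    phi = np.arctan2(d[2], d[0])
    theta_y = phi
    # wrap into [-pi/2, pi/2): beyond that the rotation would turn the
    # subject's back to the viewer; the reflection handles the sign instead
    if theta_y >= np.pi / 2:
        theta_y -= np.pi
    elif theta_y < -np.pi / 2:
        theta_y += np.pi
    Ry = _rot_y(theta_y)
    d_rot = Ry[:3, :3] @ d
    reflect = d_rot[0] < 0

    S3 = np.diag([-1.0, 1.0, 1.0]) if reflect else np.eye(3)
    both = (seq.confidence[:, _HIP] > 0) & (seq.confidence[:, _SHOULDER_C] > 0)
    if both.sum() == 0:
        torso = np.array([0.0, 1.0, 0.0])
    else:
        torso = (seq.frames[both][:, _SHOULDER_C] - seq.frames[both][:, _HIP]).mean(axis=0)
    u = S3 @ (Ry[:3, :3] @ torso)
    # zero X component in the XY plane, positive Y
    theta_z = float(np.arctan2(u[0], u[1])) if (u[0] ** 2 + u[1] ** 2) > 0 else 0.0
    return ViewTransform(T=T, theta_y=float(theta_y), reflect=bool(reflect), theta_z=theta_z)


def apply_view_transform(seq: SkeletonSequence, vt: ViewTransform) -> SkeletonSequence:
    """Map every joint p to M_view @ p (homogeneous coordinates)."""
    M = vt.M_view
    out = seq.frames @ M[:3, :3].T + M[:3, 3]
    out = out.copy()
    out[seq.confidence == 0] = 0.0  # missing joints stay at the sentinel
    return SkeletonSequence(
        layout=seq.layout, frames=out, fps=seq.fps, meta=seq.meta, confidence=seq.confidence
    )


def normalize_translation(seq: SkeletonSequence) -> SkeletonSequence:
    """Remove the global trajectory: per frame, subtract the hip center's
    X and Z from every joint.  Y is untouched so vertical gait oscillation
    survives; afterwards every frame's hip center lies on the Y axis."""
    if seq.layout is not Layout.GSI17:
        raise ValueError("translation normalization needs a GSI17 sequence")
    hip = seq.frames[:, _HIP, :].copy()
    shift = hip.copy()
    shift[:, 1] = 0.0
    out = seq.frames - shift[:, None, :]
    out[seq.confidence == 0] = 0.0
    return SkeletonSequence(
        layout=seq.layout, frames=out, fps=seq.fps, meta=seq.meta, confidence=seq.confidence
    )


def project_and_fit(
    seq: SkeletonSequence,
    canvas_w: int = 80,
    canvas_h: int = 120,
    height_margin: float = 0.9,
) -> ProjectedSequence:
    """Orthographic projection onto the canvas.

    Drops Z, computes the sequence-global bounding box over valid joints,
    applies one uniform scale so the box height equals ``height_margin`` of
    the canvas height, centers the box, and flips Y (world up becomes image
    up, with v increasing downward).  The same scale and offsets apply to
    all frames, so relative frame-to-frame motion is preserved.
    """
    xy = seq.frames[:, :, :2]
    valid = seq.confidence > 0
    if not valid.any():
        raise DegenerateTrajectoryError("no valid joints to project")
    pts = xy[valid]
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    if ymax - ymin <= 0:
        raise DegenerateTrajectoryError("zero-height bounding box")
    scale = height_margin * canvas_h / (ymax - ymin)
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    off_u = canvas_w / 2.0 - scale * cx
    off_v = canvas_h / 2.0 + scale * cy
    u = scale * xy[:, :, 0] + off_u
    v = -scale * xy[:, :, 1] + off_v
    frames = np.stack([u, v], axis=-1)
    frames[~valid] = 0.0
    return ProjectedSequence(
        frames=frames,
        confidence=seq.confidence.copy(),
        canvas_w=canvas_w,
        canvas_h=canvas_h,
        scale=float(scale),
        offsets=(float(off_u), float(off_v)),
        fps=seq.fps,
        meta=seq.meta,
    )


def normalize_sequence(seq: SkeletonSequence) -> SkeletonSequence:
    """Convenience composition: build + apply view transform, then remove
    the horizontal trajectory."""
    vt = build_view_transform(seq)
    return normalize_translation(apply_view_transform(seq, vt))
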