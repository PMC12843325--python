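"""View normalization: direction estimation, rigid alignment, isometry,
translation stabilization and canvas fitting."""

import numpy as np
import pytest

from gsigait import (
    GSI17_INDEX,
    Layout,
    SkeletonSequence,
    apply_view_transform,
    build_view_transform,
    estimate_walking_direction,
    normalize_sequence,
    normalize_translation,
    project_and_fit,
)
from gsigait.geometry import DegenerateTrajectoryError, ViewTransform, _rot_y
from gsigait.simulate import CovariateSpec, GaitParams, simulate_sequence

HIP = GSI17_INDEX["hip_center"]
SHC = GSI17_INDEX["shoulder_center"]


def _walking_seq(positions):
    """Minimal GSI17 sequence with the hip center at given positions and a
    vertical torso above it."""
    n = len(positions)
    frames = np.zeros((n, 17, 3))
    frames[:, :, :] = np.asarray(positions)[:, None, :]
    frames[:, SHC, 1] += 0.5
    frames[:, GSI17_INDEX["head"], 1] += 0.75
    return SkeletonSequence(layout=Layout.GSI17, frames=frames, fps=30.0)


def test_axis_aligned_walk_direction():
    seq = _walking_seq([[0, 1, 0], [1, 1, 0], [2, 1, 0]])
    np.testing.assert_allclose(estimate_walking_direction(seq), [1, 0, 0], atol=1e-12)


def test_diagonal_walk_with_vertical_bounce():
    t = np.linspace(0, 2, 20)
    d = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
    pos = t[:, None] * d + np.stack([np.zeros(20), 0.05 * np.sin(7 * t), np.zeros(20)], axis=1)
    seq = _walking_seq(pos)
    np.testing.assert_allclose(estimate_walking_direction(seq), d, atol=1e-6)


def test_stationary_subject_is_degenerate():
    seq = _walking_seq([[0, 1, 0], [0.001, 1, 0]])
    with pytest.raises(DegenerateTrajectoryError):
        estimate_walking_direction(seq)


def test_already_canonical_sequence_gives_identity(straight_walk):
    seq = straight_walk.copy()
    seq.frames -= seq.frames[:, HIP].mean(axis=0)
    vt = build_view_transform(seq)
    np.testing.assert_allclose(vt.M_view, np.eye(4), atol=1e-9)


def test_rotation_recovery_90_degrees(straight_walk):
    seq = straight_walk.copy()
    seq.frames -= seq.frames[:, HIP].mean(axis=0)
    rotated = seq.copy()
    rotated.frames = seq.frames @ _rot_y(np.pi / 2)[:3, :3].T
    vt = build_view_transform(rotated)
    assert vt.theta_y == pytest.approx(-np.pi / 2, abs=1e-9)
    assert not vt.reflect
    out = apply_view_transform(rotated, vt)
    np.testing.assert_allclose(out.frames, seq.frames, atol=1e-9)


def test_negative_x_walk_triggers_reflection(straight_walk):
    mirrored = straight_walk.copy()
    mirrored.frames = straight_walk.frames * [-1, 1, 1]
    vt = build_view_transform(mirrored)
    assert vt.reflect
    np.testing.assert_allclose(vt.S, np.diag([-1.0, 1, 1, 1]))
    out = apply_view_transform(mirrored, vt)
    hips = out.frames[:, HIP, 0]
    assert hips[-1] > hips[0]  # walks along +X again


def test_reflection_flips_rotation_block_determinant(straight_walk):
    vt = build_view_transform(straight_walk)
    assert np.linalg.det(vt.M_view[:3, :3]) == pytest.approx(1.0, abs=1e-9)
    mirrored = straight_walk.copy()
    mirrored.frames = straight_walk.frames * [-1, 1, 1]
    vtm = build_view_transform(mirrored)
    assert np.linalg.det(vtm.M_view[:3, :3]) == pytest.approx(-1.0, abs=1e-9)


def test_factorization_is_exact(straight_walk):
    from gsigait.geometry import _rot_z
    vt = build_view_transform(straight_walk)
    M = _rot_z(vt.theta_z) @ vt.S @ _rot_y(vt.theta_y) @ vt.T
    np.testing.assert_array_equal(vt.M_view, M)


def test_identity_and_pure_translation():
    vt = ViewTransform(T=np.eye(4), theta_y=0.0, reflect=False, theta_z=0.0)
    frames = np.random.default_rng(0).normal(size=(2, 17, 3))
    seq = SkeletonSequence(layout=Layout.GSI17, frames=frames, fps=30.0)
    np.testing.assert_array_equal(apply_view_transform(seq, vt).frames, frames)

    T = np.eye(4)
    T[:3, 3] = [-1, -2, -3]
    vt = ViewTransform(T=T, theta_y=0.0, reflect=False, theta_z=0.0)
    frames = np.ones((2, 17, 3)) * [1.0, 2.0, 3.0]
    seq = SkeletonSequence(layout=Layout.GSI17, frames=frames, fps=30.0)
    np.testing.assert_allclose(apply_view_transform(seq, vt).frames, 0.0, atol=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_isometry_random_rigid_transforms(seed):
    """Pairwise intra-frame distances are preserved to 1e-9."""
    rng = np.random.default_rng(seed)
    frames = rng.normal(size=(3, 17, 3))
    seq = SkeletonSequence(layout=Layout.GSI17, frames=frames, fps=30.0)
    T = np.eye(4)
    T[:3, 3] = rng.normal(size=3)
    vt = ViewTransform(T=T, theta_y=rng.uniform(-np.pi, np.pi),
                       reflect=bool(rng.integers(2)), theta_z=rng.uniform(-np.pi, np.pi))
    out = apply_view_transform(seq, vt)
    for i in range(frames.shape[0]):
        d0 = np.linalg.norm(frames[i][:, None] - frames[i][None], axis=-1)
        d1 = np.linalg.norm(out.frames[i][:, None] - out.frames[i][None], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)


def test_normalize_translation_moves_hip_to_y_axis():
    rng = np.random.default_rng(2)
    frames = rng.normal(size=(5, 17, 3))
    seq = SkeletonSequence(layout=Layout.GSI17, frames=frames, fps=30.0)
    out = normalize_translation(seq)
    np.testing.assert_allclose(out.frames[:, HIP, 0], 0.0, atol=1e-12)
    np.testing.assert_allclose(out.frames[:, HIP, 2], 0.0, atol=1e-12)
    # Y untouched
    np.testing.assert_array_equal(out.frames[:, :, 1], frames[:, :, 1])


def test_translating_constant_pose_collapses_to_identical_frames():
    pose = np.random.default_rng(3).normal(size=(17, 3))
    shifts = np.linspace(0, 3, 6)
    frames = pose[None] + np.stack([shifts, 0 * shifts, 0 * shifts], axis=1)[:, None, :]
    seq = SkeletonSequence(layout=Layout.GSI17, frames=frames, fps=30.0)
    out = normalize_translation(seq)
    for i in range(1, 6):
        np.testing.assert_allclose(out.frames[i], out.frames[0], atol=1e-12)


def test_project_fit_arithmetic():
    """Two points one meter apart vertically span 90% of the canvas height
    and sit horizontally centered."""
    frames = np.zeros((2, 17, 3))
    frames[:, 1:, 1] = 1.0  # joint 0 at y=0, the rest at y=1
    seq = SkeletonSequence(layout=Layout.GSI17, frames=frames, fps=30.0)
    proj = project_and_fit(seq, canvas_w=80, canvas_h=120)
    v = proj.frames[0, :, 1]
    assert v.max() - v.min() == pytest.approx(108.0, abs=1e-9)
    np.testing.assert_allclose(proj.frames[..., 0], 40.0, atol=1e-9)


def test_projection_scale_invariance():
    rng = np.random.default_rng(4)
    frames = rng.normal(size=(3, 17, 3))
    seq = SkeletonSequence(layout=Layout.GSI17, frames=frames, fps=30.0)
    doubled = SkeletonSequence(layout=Layout.GSI17, frames=2 * frames, fps=30.0)
    p1, p2 = project_and_fit(seq), project_and_fit(doubled)
    np.testing.assert_allclose(p1.frames, p2.frames, atol=1e-9)


def test_zero_height_box_is_degenerate():
    seq = SkeletonSequence(layout=Layout.GSI17, frames=np.zeros((2, 17, 3)), fps=30.0)
    with pytest.raises(DegenerateTrajectoryError):
        project_and_fit(seq)


def test_mirror_consistency_full_pipeline(straight_walk):
    """A left-to-right walk and its mirrored right-to-left twin normalize
    to the same projected sequence."""
    mirrored = straight_walk.copy()
    mirrored.frames = straight_walk.frames * [-1, 1, 1]
    p1 = project_and_fit(normalize_sequence(straight_walk))
    p2 = project_and_fit(normalize_sequence(mirrored))
    np.testing.assert_allclose(p2.frames, p1.frames, atol=1e-6)


def test_view_normalization_idempotent(straight_walk):
    """Re-estimating the view transform on a view-normalized sequence
    yields the identity."""
    once = apply_view_transform(straight_walk, build_view_transform(straight_walk))
    vt = build_view_transform(once)
    np.testing.assert_allclose(vt.M_view, np.eye(4), atol=1e-9)
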