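"""Rasterization against a brute-force per-pixel distance oracle,
accumulation identities, and the end-to-end template pipeline."""

import numpy as np
import pytest

from gsigait import (
    RenderParams,
    RunConfig,
    accumulate,
    compute_gei,
    compute_gsi,
    rasterize_joints,
    rasterize_lines,
    sweep_params,
)
from gsigait.io import SilhouetteStack
from gsigait.simulate import CovariateSpec, GaitParams, simulate_sequence
from gsigait.topology import GSI17_EDGES


def _point_segment_dist(px, py, a, b):
    d = b - a
    len2 = d @ d
    if len2 == 0:
        return np.hypot(px - a[0], py - a[1])
    t = np.clip(((px - a[0]) * d[0] + (py - a[1]) * d[1]) / len2, 0, 1)
    return np.hypot(px - (a[0] + t * d[0]), py - (a[1] + t * d[1]))


def brute_force_lines(frame, thickness, conf=None, w=80, h=120):
    """O(W*H*edges) membership test evaluated for every pixel center."""
    img = np.zeros((h, w), np.uint8)
    for i in range(h):
        for j in range(w):
            for a, b in GSI17_EDGES:
                if conf is not None and (conf[a] <= 0 or conf[b] <= 0):
                    continue
                if _point_segment_dist(j + 0.5, i + 0.5, frame[a], frame[b]) <= thickness / 2:
                    img[i, j] = 1
                    break
    return img


def brute_force_joints(frame, radius, conf=None, w=80, h=120):
    img = np.zeros((h, w), np.uint8)
    for i in range(h):
        for j in range(w):
            for k in range(frame.shape[0]):
                if conf is not None and conf[k] <= 0:
                    continue
                if np.hypot(j + 0.5 - frame[k, 0], i + 0.5 - frame[k, 1]) <= radius:
                    img[i, j] = 1
                    break
    return img


def _random_frames(n, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform([-10, -10], [90, 130], size=(n, 17, 2))


@pytest.mark.parametrize("value", [2, 8, 12])
def test_line_rasterization_matches_brute_force(value):
    params = RenderParams(variant="lines", thickness_px=value)
    for frame in _random_frames(6, seed=value):
        got = rasterize_lines(frame, params)
        np.testing.assert_array_equal(got, brute_force_lines(frame, value))


@pytest.mark.parametrize("value", [2, 8, 12])
def test_joint_rasterization_matches_brute_force(value):
    params = RenderParams(variant="joints", radius_px=value)
    for frame in _random_frames(6, seed=100 + value):
        got = rasterize_joints(frame, params)
        np.testing.assert_array_equal(got, brute_force_joints(frame, value))


def test_single_horizontal_edge_capsule_count():
    frame = np.zeros((17, 2))
    conf = np.zeros(17)
    frame[1], frame[0] = [10.0, 60.0], [30.0, 60.0]  # head-neck edge
    conf[0] = conf[1] = 1.0
    got = rasterize_lines(frame, RenderParams(variant="lines", thickness_px=2), conf)
    expected = brute_force_lines(frame, 2, conf)
    np.testing.assert_array_equal(got, expected)
    assert got.sum() == expected.sum() > 0


def test_zero_length_edge_is_a_disc():
    frame = np.full((17, 2), -100.0)
    conf = np.zeros(17)
    frame[0] = frame[1] = [40.0, 60.0]  # coincident head and neck
    conf[0] = conf[1] = 1.0
    got = rasterize_lines(frame, RenderParams(variant="lines", thickness_px=8), conf)
    disc = brute_force_joints(frame[:2], 4.0, np.ones(2))
    np.testing.assert_array_equal(got, disc)


def test_all_invalid_joints_give_blank_images():
    frame = _random_frames(1)[0]
    conf = np.zeros(17)
    assert rasterize_lines(frame, RenderParams(variant="lines"), conf).sum() == 0
    assert rasterize_joints(frame, RenderParams(variant="joints"), conf).sum() == 0


def test_disc_pixel_count_near_area():
    frame = np.full((17, 2), -100.0)
    conf = np.zeros(17)
    frame[0] = [40.0, 60.0]
    conf[0] = 1.0
    got = rasterize_joints(frame, RenderParams(variant="joints", radius_px=8), conf)
    assert got.sum() == pytest.approx(np.pi * 64, rel=0.05)


def test_offcanvas_keypoint_no_overlap_is_blank():
    frame = np.full((17, 2), 500.0)
    got = rasterize_joints(frame, RenderParams(variant="joints", radius_px=2))
    assert got.sum() == 0


def test_coincident_keypoints_idempotent_union():
    frame = np.full((17, 2), -100.0)
    conf = np.zeros(17)
    frame[0] = frame[5] = [40.0, 60.0]
    conf[0] = 1.0
    one = rasterize_joints(frame, RenderParams(variant="joints", radius_px=6), conf)
    conf[5] = 1.0
    two = rasterize_joints(frame, RenderParams(variant="joints", radius_px=6), conf)
    np.testing.assert_array_equal(one, two)


@pytest.mark.parametrize("variant", ["lines", "joints"])
def test_footprint_monotone_in_parameter(variant):
    """Pixel set at parameter a is a subset of the set at b >= a."""
    frames = _random_frames(5, seed=9)
    prev = None
    for value in (1, 2, 4, 8, 12):
        params = RenderParams(variant=variant, thickness_px=value, radius_px=value)
        imgs = [
            rasterize_lines(f, params) if variant == "lines" else rasterize_joints(f, params)
            for f in frames
        ]
        cur = np.stack(imgs)
        if prev is not None:
            assert np.all(cur[prev.astype(bool)] == 1)
        prev = cur


def test_accumulate_identities():
    rng = np.random.default_rng(1)
    frame = (rng.random((120, 80)) < 0.3).astype(np.uint8)
    np.testing.assert_array_equal(accumulate([frame] * 5), frame.astype(float))
    np.testing.assert_allclose(accumulate([frame, np.zeros_like(frame)]), frame / 2.0)
    with pytest.raises(ValueError):
        accumulate([])


def test_accumulate_matches_brute_force_sum():
    rng = np.random.default_rng(2)
    stack = (rng.random((7, 40, 30)) < 0.5).astype(np.uint8)
    expected = sum(f.astype(float) for f in stack) / 7.0
    np.testing.assert_allclose(accumulate(list(stack)), expected, atol=1e-12)


def test_template_support_equals_union_mask():
    rng = np.random.default_rng(3)
    stack = (rng.random((5, 20, 20)) < 0.2).astype(np.uint8)
    t = accumulate(list(stack))
    np.testing.assert_array_equal(t > 0, stack.any(axis=0))


@pytest.fixture(scope="module")
def walk():
    return simulate_sequence(GaitParams(), CovariateSpec(), 4.0, 30.0, 0.0, seed=0)


def test_compute_gsi_sanity_and_determinism(walk, default_cfg):
    t1 = compute_gsi(walk, default_cfg)
    t2 = compute_gsi(walk, default_cfg)
    assert 0.05 < (t1.pixels > 0).mean() < 0.9
    np.testing.assert_array_equal(t1.pixels, t2.pixels)


def test_view_invariance_of_templates(default_cfg):
    """The same noise-free gait seen at 0 and 90 degrees gives near
    identical templates once normalized."""
    p = GaitParams()
    t0 = compute_gsi(simulate_sequence(p, CovariateSpec(view_deg=0.0), 4.0, 30.0, 0.0, 0), default_cfg)
    t90 = compute_gsi(simulate_sequence(p, CovariateSpec(view_deg=90.0), 4.0, 30.0, 0.0, 0), default_cfg)
    assert np.abs(t0.pixels - t90.pixels).mean() <= 0.02


def test_gei_identities():
    rng = np.random.default_rng(4)
    sil = (rng.random((6, 120, 80)) < 0.4).astype(np.uint8)
    stack = SilhouetteStack(frames=np.repeat(sil[:1], 4, axis=0), fps=30.0)
    t = compute_gei(stack, align=False)
    np.testing.assert_array_equal(t.pixels, sil[0].astype(float))
    one = SilhouetteStack(frames=sil[:1], fps=30.0)
    np.testing.assert_array_equal(compute_gei(one, align=False).pixels, sil[0].astype(float))
    full = compute_gei(SilhouetteStack(frames=sil, fps=30.0), align=False)
    np.testing.assert_allclose(full.pixels, sil.mean(axis=0), atol=1e-12)


def test_sweep_monotone_and_consistent(walk, default_cfg):
    result = sweep_params([walk], [2, 8], default_cfg)
    assert set(result) == {2, 8}
    frac2 = (result[2][0].pixels > 0).mean()
    frac8 = (result[8][0].pixels > 0).mean()
    assert frac8 > frac2
    np.testing.assert_array_equal(result[8][0].pixels, compute_gsi(walk, default_cfg).pixels)
    with pytest.raises(ValueError):
        sweep_params([walk], [])
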