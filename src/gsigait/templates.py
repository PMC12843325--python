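"""Template rendering: per-frame skeleton rasterization and temporal
accumulation into gait templates, plus the silhouette-averaging baseline.

Two skeletal variants are produced.  The line variant draws each bone as a
capsule (stadium) of a given thickness between its two joints; the joint
variant draws a disc of a given radius at each joint.  Per-frame images are
binary — a pixel is set iff its center lies within the footprint — and the
template is their pixel-wise mean, so values in [0, 1] read as occupancy
frequency over the cycle, exactly as in silhouette energy images.

Rasterization is a hard geometric membership test with no anti-aliasing:
the result is exactly reproducible and equals a brute-force per-pixel
distance evaluation (the implementation only restricts the test to the
footprint's bounding box).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .cycles import segment_cycles
from .geometry import (
    ProjectedSequence,
    apply_view_transform,
    build_view_transform,
    normalize_translation,
    project_and_fit,
)
from .io import GaitTemplate, RunConfig, SilhouetteStack, SkeletonSequence
from .topology import GSI17_EDGES, to_gsi17

__all__ = [
    "RenderParams",
    "rasterize_lines",
    "rasterize_joints",
    "accumulate",
    "compute_gsi",
    "compute_gei",
    "sweep_params",
    "DEFAULT_SWEEP_VALUES",
]

DEFAULT_SWEEP_VALUES = (2, 4, 6, 8, 10, 12)


@dataclass
class RenderParams:
    variant: str  # lines / joints
    thickness_px: int = 8  # line variant
    radius_px: int = 8  # joint variant
    canvas_w: int = 80
    canvas_h: int = 120

    def __post_init__(self) -> None:
        if self.variant not in ("lines", "joints"):
            raise ValueError("variant must be 'lines' or 'joints'")
        if self.thickness_px < 1 or self.radius_px < 1:
            raise ValueError("thickness/radius must be >= 1")

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "RenderParams":
        return cls(
            variant=cfg.variant,
            thickness_px=cfg.thickness_px,
            radius_px=cfg.radius_px,
            canvas_w=cfg.canvas_w,
            canvas_h=cfg.canvas_h,
        )


def _pixel_centers(w: int, h: int):
    # pixel (row i, col j) has center (u, v) = (j + 0.5, i + 0.5)
    u = np.arange(w) + 0.5
    v = np.arange(h) + 0.5
    return u, v


def _stamp_capsule(img: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float) -> None:
    """Set pixels whose center is within `radius` of segment p0-p1."""
    h, w = img.shape
    lo = np.floor(np.minimum(p0, p1) - radius - 0.5).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius + 0.5).astype(int)
    j0, i0 = max(lo[0], 0), max(lo[1], 0)
    j1, i1 = min(hi[0] + 1, w), min(hi[1] + 1, h)
    if j0 >= j1 or i0 >= i1:
        return
    uu = np.arange(j0, j1) + 0.5
    vv = np.arange(i0, i1) + 0.5
    U, V = np.meshgrid(uu, vv)
    d = p1 - p0
    len2 = d @ d
    if len2 == 0:
        dist2 = (U - p0[0]) ** 2 + (V - p0[1]) ** 2
    else:
        t = ((U - p0[0]) * d[0] + (V - p0[1]) * d[1]) / len2
        t = np.clip(t, 0.0, 1.0)
        dist2 = (U - (p0[0] + t * d[0])) ** 2 + (V - (p0[1] + t * d[1])) ** 2
    img[i0:i1, j0:j1] |= dist2 <= radius * radius


def rasterize_lines(
    frame: np.ndarray,
    params: RenderParams,
    confidence: Optional[np.ndarray] = None,
    edges: Sequence = GSI17_EDGES,
) -> np.ndarray:
    """Binary image of the skeleton's bones drawn as capsules of width
    ``thickness_px``.  Edges with an invalid endpoint (confidence 0) are
    skipped, never extrapolated."""
    if params.variant != "lines":
        raise ValueError("params.variant must be 'lines'")
    img = np.zeros((params.canvas_h, params.canvas_w), dtype=bool)
    r = params.thickness_px / 2.0
    for a, b in edges:
        if confidence is not None and (confidence[a] <= 0 or confidence[b] <= 0):
            continue
        _stamp_capsule(img, np.asarray(frame[a], float), np.asarray(frame[b], float), r)
    return img.astype(np.uint8)


def rasterize_joints(
    frame: np.ndarray,
    params: RenderParams,
    confidence: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Binary image with a disc of radius ``radius_px`` at each valid
    keypoint; discs clip at the canvas border."""
    if params.variant != "joints":
        raise ValueError("params.variant must be 'joints'")
    img = np.zeros((params.canvas_h, params.canvas_w), dtype=bool)
    r = float(params.radius_px)
    for k in range(frame.shape[0]):
        if confidence is not None and confidence[k] <= 0:
            continue
        p = np.asarray(frame[k], float)
        _stamp_capsule(img, p, p, r)
    return img.astype(np.uint8)


def accumulate(frames: List[np.ndarray], mode: str = "mean") -> np.ndarray:
    """Pixel-wise mean (or max) of a stack of binary frames -> [0, 1]."""
    if len(frames) == 0:
        raise ValueError("cannot accumulate an empty frame list")
    stack = np.stack([np.asarray(f, dtype=float) for f in frames])
    if stack.ndim != 3:
        raise ValueError("frames must share identical 2-D dimensions")
    if mode == "mean":
        return stack.mean(axis=0)
    if mode == "max":
        return stack.max(axis=0)
    raise ValueError("mode must be 'mean' or 'max'")


def _rasterize_sequence(proj: ProjectedSequence, params: RenderParams, frame_range=None):
    lo, hi = (0, proj.frames.shape[0]) if frame_range is None else frame_range
    out = []
    for i in range(lo, hi):
        if params.variant == "lines":
            out.append(rasterize_lines(proj.frames[i], params, proj.confidence[i]))
        else:
            out.append(rasterize_joints(proj.frames[i], params, proj.confidence[i]))
    return out


def compute_gsi(seq: SkeletonSequence, cfg: RunConfig) -> GaitTemplate:
    """Full skeletal-template pipeline for one sequence.

    Stages: layout conversion (if needed) -> view normalization ->
    horizontal-trajectory removal -> orthographic projection and canvas fit
    -> gait-cycle segmentation -> per-frame rasterization -> temporal
    accumulation.  Deterministic: identical input and config give a
    bit-identical template.
    """
    if cfg.variant not in ("lines", "joints"):
        raise ValueError("compute_gsi needs variant 'lines' or 'joints'")
    g = to_gsi17(seq)
    vt = build_view_transform(g)
    g = normalize_translation(apply_view_transform(g, vt))
    proj = project_and_fit(g, cfg.canvas_w, cfg.canvas_h, cfg.height_margin)
    segm = segment_cycles(proj, fps=seq.fps)
    params = RenderParams.from_config(cfg)
    lo, hi = segm.boundaries[0], segm.boundaries[-1]
    frames = _rasterize_sequence(proj, params, (lo, hi))
    pixels = accumulate(frames, cfg.accumulate)
    par = {"thickness_px": cfg.thickness_px} if cfg.variant == "lines" else {"radius_px": cfg.radius_px}
    return GaitTemplate(
        pixels=pixels, variant=cfg.variant, params=par, n_frames=len(frames), meta=seq.meta
    )


def compute_gsi_per_cycle(seq: SkeletonSequence, cfg: RunConfig) -> List[GaitTemplate]:
    """One template per detected gait cycle (option to the per-sequence default)."""
    g = to_gsi17(seq)
    vt = build_view_transform(g)
    g = normalize_translation(apply_view_transform(g, vt))
    proj = project_and_fit(g, cfg.canvas_w, cfg.canvas_h, cfg.height_margin)
    segm = segment_cycles(proj, fps=seq.fps)
    params = RenderParams.from_config(cfg)
    out = []
    par = {"thickness_px": cfg.thickness_px} if cfg.variant == "lines" else {"radius_px": cfg.radius_px}
    for lo, hi in segm.cycles():
        frames = _rasterize_sequence(proj, params, (lo, hi))
        out.append(
            GaitTemplate(
                pixels=accumulate(frames, cfg.accumulate),
                variant=cfg.variant,
                params=par,
                n_frames=len(frames),
                meta=seq.meta,
            )
        )
    return out


def _align_silhouette(frame: np.ndarray, canvas_w: int, canvas_h: int, margin: float) -> np.ndarray:
    """Size-normalize one binary silhouette: height scaled to `margin` of the
    canvas, horizontal center of mass at the canvas center."""
    rows = np.flatnonzero(frame.any(axis=1))
    cols = np.flatnonzero(frame.any(axis=0))
    if rows.size == 0:
        return np.zeros((canvas_h, canvas_w), dtype=np.uint8)
    crop = frame[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1].astype(float)
    target_h = margin * canvas_h
    zoom = target_h / crop.shape[0]
    resized = ndimage.zoom(crop, zoom, order=1, prefilter=False) >= 0.5
    rh, rw = resized.shape
    out = np.zeros((canvas_h, canvas_w), dtype=np.uint8)
    top = int(round((canvas_h - rh) / 2.0))
    # horizontal center of mass -> canvas center
    com = ndimage.center_of_mass(resized)[1]
    left = int(round(canvas_w / 2.0 - com))
    for i in range(rh):
        oi = top + i
        if not (0 <= oi < canvas_h):
            continue
        js = np.flatnonzero(resized[i])
        for j in js:
            oj = left + j
            if 0 <= oj < canvas_w:
                out[oi, oj] = 1
    return out


def compute_gei(
    sil: SilhouetteStack,
    canvas_w: int = 80,
    canvas_h: int = 120,
    height_margin: float = 0.9,
    align: bool = True,
) -> GaitTemplate:
    """Energy image: pixel-wise mean of size-normalized binary silhouettes."""
    if sil.n_frames == 0:
        raise ValueError("empty silhouette stack")
    if align:
        frames = [_align_silhouette(f, canvas_w, canvas_h, height_margin) for f in sil.frames]
    else:
        frames = [f for f in sil.frames]
    pixels = accumulate(frames, "mean")
    return GaitTemplate(pixels=pixels, variant="gei", params={}, n_frames=len(frames), meta=sil.meta)


def sweep_params(
    seqs: Iterable[SkeletonSequence],
    values: Sequence[int] = DEFAULT_SWEEP_VALUES,
    cfg: Optional[RunConfig] = None,
) -> dict:
    """Render every sequence at every thickness/radius value.

    Returns {value: [GaitTemplate, ...]}.  The downstream default stays at
    8 px, where template density best balances continuity against smoothing.
    """
    values = list(values)
    if not values:
        raise ValueError("sweep needs a nonempty value list")
    cfg = cfg or RunConfig()
    seqs = list(seqs)
    out = {}
    for v in values:
        cv = dataclasses.replace(cfg, thickness_px=int(v), radius_px=int(v))
        out[int(v)] = [compute_gsi(s, cv) for s in seqs]
    return out
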