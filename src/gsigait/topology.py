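"""The 17-keypoint gait body model and conversions from source pose layouts.

The body model keeps the joints that carry gait information — the axial
chain (head, neck, shoulder center, spine center, hip center) and the
bilateral limb chains down to wrists and ankles — and drops hand, foot and
facial landmarks, whose tracking is least reliable at gait-analysis
distances.  The 16 bones form a kinematic tree with no left-to-right limb
link except through the axial chain.

Conversion rules (direct mappings, computed midpoints, discarded joints)
are shipped as a YAML data file so they are inspectable and testable
outside the code path that applies them.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .io import Layout, LayoutError, SkeletonSequence

__all__ = [
    "GSI17_KEYPOINTS",
    "GSI17_EDGES",
    "GSI17_INDEX",
    "load_mappings",
    "map_kinect25_to_gsi17",
    "map_mediapipe33_to_gsi17",
    "to_gsi17",
]


@lru_cache(maxsize=1)
def load_mappings() -> dict:
    """Load the layout-conversion rule tables shipped with the package."""
    with resources.files("gsigait.data").joinpath("mappings.yaml").open() as fh:
        return yaml.safe_load(fh)


_M = load_mappings()

GSI17_KEYPOINTS: tuple = tuple(_M["gsi17"]["keypoints"])
GSI17_INDEX: dict = {name: i for i, name in enumerate(GSI17_KEYPOINTS)}
GSI17_EDGES: tuple = tuple(
    (GSI17_INDEX[a], GSI17_INDEX[b]) for a, b in _M["gsi17"]["edges"]
)

assert len(GSI17_KEYPOINTS) == 17 and len(GSI17_EDGES) == 16


def _convert(seq: SkeletonSequence, table: dict, expected: Layout) -> SkeletonSequence:
    if seq.layout is not expected:
        raise LayoutError(f"expected layout {expected.name}, got {seq.layout.name}")
    src_index = {name: i for i, name in enumerate(table["joints"])}
    frames = seq.frames
    if table.get("negate_z"):
        frames = frames * np.array([1.0, 1.0, -1.0])
    n = seq.n_frames
    out = np.zeros((n, 17, 3))
    conf = np.zeros((n, 17))

    produced: dict = {}
    for gsi_name, src_name in table["direct"].items():
        j = src_index[src_name]
        k = GSI17_INDEX[gsi_name]
        out[:, k] = frames[:, j]
        conf[:, k] = seq.confidence[:, j]
        produced[gsi_name] = k
    # Midpoints evaluated in listed order; a "gsi:" source refers to an
    # already-produced target keypoint, otherwise to a source-layout joint.
    for gsi_name, sources in table.get("midpoints", {}).items():
        pts, cfs = [], []
        for s in sources:
            if s.startswith("gsi:"):
                k = produced[s[4:]]
                pts.append(out[:, k])
                cfs.append(conf[:, k])
            else:
                j = src_index[s]
                pts.append(frames[:, j])
                cfs.append(seq.confidence[:, j])
        k = GSI17_INDEX[gsi_name]
        out[:, k] = np.mean(pts, axis=0)
        conf[:, k] = np.min(cfs, axis=0)  # conservative: weakest source dominates
        produced[gsi_name] = k

    # A missing joint keeps the (0,0,0) convention.
    out[conf == 0] = 0.0
    return SkeletonSequence(
        layout=Layout.GSI17, frames=out, fps=seq.fps, meta=seq.meta, confidence=conf
    )


def map_kinect25_to_gsi17(seq: SkeletonSequence) -> SkeletonSequence:
    """Convert a Kinect-v2 25-joint sequence (direct mappings only).

    Kinect's z axis points away from the camera, so z is negated to match
    the package convention before mapping.
    """
    return _convert(seq, load_mappings()["kinect25"], Layout.KINECT25)


def map_mediapipe33_to_gsi17(seq: SkeletonSequence) -> SkeletonSequence:
    """Convert a MediaPipe 33-landmark sequence.

    The four central-axis keypoints are computed midpoints: shoulder center
    and hip center from the bilateral pairs, spine center from those two,
    neck from head (nose) and shoulder center.  Facial, hand and foot
    landmarks are discarded.
    """
    return _convert(seq, load_mappings()["mediapipe33"], Layout.MEDIAPIPE33)


def to_gsi17(seq: SkeletonSequence) -> SkeletonSequence:
    """Dispatch on layout; a GSI17 sequence passes through unchanged."""
    if seq.layout is Layout.GSI17:
        return seq
    if seq.layout is Layout.KINECT25:
        return map_kinect25_to_gsi17(seq)
    if seq.layout is Layout.MEDIAPIPE33:
        return map_mediapipe33_to_gsi17(seq)
    raise LayoutError(f"no conversion from layout {seq.layout}")
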