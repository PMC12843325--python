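"""Sequence, silhouette and template I/O, plus run configuration.

Skeleton sequences live in a single camera-frame convention throughout the
package: x to the right, y up, z toward the camera, coordinates in meters.
Source layouts whose native axes differ (Kinect v2's z points away from the
camera) are adapted by the converters in :mod:`gsigait.topology`.

On-disk sequence format is JSON lines: a header object
``{"layout": ..., "fps": ..., "meta": {...}}`` followed by one object per
frame, ``{"t": <index>, "joints": [[x, y, z], ...], "conf": [...]}``.
Floats are serialized with full ``repr`` precision, so a write/read
round-trip is bit-identical.  Templates are stored as 8-bit grayscale PNG
(value ``v`` in [0, 1] stored as ``round(v * 255)``).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from PIL import Image

logger = logging.getLogger("gsigait")

__all__ = [
    "Layout",
    "SequenceMeta",
    "SkeletonSequence",
    "SilhouetteStack",
    "GaitTemplate",
    "RunConfig",
    "read_sequence",
    "write_sequence",
    "read_template",
    "write_template",
    "read_silhouettes",
    "write_silhouettes",
]


class Layout(enum.Enum):
    """Named joint layouts with their fixed per-frame joint counts."""

    KINECT25 = 25
    MEDIAPIPE33 = 33
    GSI17 = 17

    @property
    def n_joints(self) -> int:
        return self.value


class LayoutError(ValueError):
    """Per-frame joint count does not match the declared layout."""


class ParseError(ValueError):
    """Malformed sequence record; message names the offending line."""


@dataclass
class SequenceMeta:
    subject: str = ""
    trial: str = ""
    view_deg: Optional[float] = None
    covariate: Optional[str] = None  # NM / BG / CL

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceMeta":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class SkeletonSequence:
    """Ordered 3D joint frames in a named layout.

    ``frames`` has shape (n_frames, n_joints, 3) in meters, camera frame.
    ``confidence`` has shape (n_frames, n_joints) in [0, 1]; a joint is
    missing iff its confidence is exactly 0 (its coordinates are then
    conventionally (0, 0, 0) on disk but are never interpreted).
    """

    layout: Layout
    frames: np.ndarray
    fps: float
    meta: SequenceMeta = field(default_factory=SequenceMeta)
    confidence: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (n, joints, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if self.frames.shape[1] != self.layout.n_joints:
            raise LayoutError(
                f"layout {self.layout.name} expects {self.layout.n_joints} joints "
                f"per frame, got {self.frames.shape[1]}"
            )
        if not np.isfinite(self.frames).all():
            raise ValueError("joint coordinates must be finite (no NaN/Inf)")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.confidence is None:
            self.confidence = np.ones(self.frames.shape[:2])
        else:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != self.frames.shape[:2]:
                raise ValueError("confidence shape must be (n_frames, n_joints)")
            if ((self.confidence < 0) | (self.confidence > 1)).any():
                raise ValueError("confidence values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def copy(self) -> "SkeletonSequence":
        return SkeletonSequence(
            layout=self.layout,
            frames=self.frames.copy(),
            fps=self.fps,
            meta=dataclasses.replace(self.meta),
            confidence=self.confidence.copy(),
        )


@dataclass
class SilhouetteStack:
    """Ordered binary silhouette images of identical size."""

    frames: np.ndarray  # (n, H, W), values in {0, 1}
    fps: float
    meta: SequenceMeta = field(default_factory=SequenceMeta)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("silhouette frames must be (n, H, W)")
        vals = np.unique(self.frames)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("silhouette pixels must be 0/1")
        self.frames = self.frames.astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class GaitTemplate:
    """Fixed-size grayscale motion template with values in [0, 1]."""

    pixels: np.ndarray  # (H, W) floats in [0, 1]
    variant: str  # lines / joints / gei
    params: dict = field(default_factory=dict)
    n_frames: int = 1
    meta: SequenceMeta = field(default_factory=SequenceMeta)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("template pixels must be 2-D")
        if not np.isfinite(self.pixels).all():
            raise ValueError("template pixels must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("template values must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


_VARIANTS = ("lines", "joints", "gei")
_PROTOCOLS = ("loto", "gallery_probe")


@dataclass
class RunConfig:
    """Run-level configuration shared across pipeline stages.

    ``thickness_px`` applies to the line variant, ``radius_px`` to the joint
    variant; the 8-pixel default is the setting at which both template
    variants are densest without smoothing away kinematic detail.
    """

    variant: str = "joints"
    thickness_px: int = 8
    radius_px: int = 8
    canvas_w: int = 80
    canvas_h: int = 120
    height_margin: float = 0.9  # template bounding box fills 90% of canvas height
    accumulate: str = "mean"  # or "max"
    per_cycle: bool = False  # one template per detected gait cycle instead of per sequence
    seed: int = 0
    protocol: str = "loto"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if self.protocol not in _PROTOCOLS:
            raise ValueError(f"protocol must be one of {_PROTOCOLS}")
        for name in ("thickness_px", "radius_px"):
            v = getattr(self, name)
            if not (1 <= int(v) <= 64):
                raise ValueError(f"{name} must be in 1..64, got {v}")
        if self.canvas_w < 16 or self.canvas_h < 16:
            raise ValueError("canvas dimensions must be >= 16")
        if self.accumulate not in ("mean", "max"):
            raise ValueError("accumulate must be 'mean' or 'max'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# skeleton sequences


def write_sequence(seq: SkeletonSequence, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        header = {
            "layout": seq.layout.name,
            "fps": seq.fps,
            "meta": seq.meta.to_dict(),
        }
        fh.write(json.dumps(header) + "\n")
        for i in range(seq.n_frames):
            rec = {
                "t": i,
                "joints": seq.frames[i].tolist(),
                "conf": seq.confidence[i].tolist(),
            }
            fh.write(json.dumps(rec) + "\n")


def read_sequence(path, layout: Optional[Layout] = None) -> SkeletonSequence:
    """Read a JSON-lines skeleton sequence.

    ``layout``, if given, must match the header's declared layout.  Missing
    joints (confidence 0) keep the conventional (0, 0, 0) coordinates.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: malformed header at line 1: {e}") from e
    try:
        file_layout = Layout[header["layout"]]
    except KeyError as e:
        raise ParseError(f"{path}: header missing/unknown layout: {e}") from e
    if layout is not None and layout is not file_layout:
        raise LayoutError(
            f"{path}: declared layout {layout.name} but file header says {file_layout.name}"
        )
    fps = float(header.get("fps", 30.0))
    meta = SequenceMeta.from_dict(header.get("meta", {}))

    frames, confs = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            joints = np.asarray(rec["joints"], dtype=float)
            conf = rec.get("conf")
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as e:
            raise ParseError(f"{path}: malformed frame record at line {lineno}: {e}") from e
        if joints.ndim != 2 or joints.shape[1] != 3:
            raise ParseError(f"{path}: frame at line {lineno} is not a list of [x,y,z]")
        if joints.shape[0] != file_layout.n_joints:
            raise LayoutError(
                f"{path}: frame at line {lineno} (frame {lineno - 1}) has "
                f"{joints.shape[0]} joints, layout {file_layout.name} expects "
                f"{file_layout.n_joints}"
            )
        frames.append(joints)
        confs.append(
            np.ones(joints.shape[0]) if conf is None else np.asarray(conf, dtype=float)
        )
    return SkeletonSequence(
        layout=file_layout,
        frames=np.stack(frames),
        fps=fps,
        meta=meta,
        confidence=np.stack(confs),
    )


# ---------------------------------------------------------------------------
# templates and silhouettes


def write_template(t: GaitTemplate, path) -> None:
    """Write a template as 8-bit grayscale PNG (v stored as round(v*255))."""
    if t.pixels.min() < 0 or t.pixels.max() > 1:
        raise ValueError("template values out of [0, 1]")
    arr = np.round(t.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path), format="PNG")


def read_template(path, variant: str = "gei", params: Optional[dict] = None) -> GaitTemplate:
    arr = np.asarray(Image.open(Path(path)).convert("L"), dtype=float) / 255.0
    return GaitTemplate(pixels=arr, variant=variant, params=params or {})


def write_silhouettes(stack: SilhouetteStack, directory, prefix: str = "sil") -> list:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(stack.n_frames):
        p = directory / f"{prefix}_{i:05d}.png"
        Image.fromarray(stack.frames[i] * 255, mode="L").save(p, format="PNG")
        paths.append(p)
    return paths


def read_silhouettes(paths, fps: float = 30.0, meta: Optional[SequenceMeta] = None) -> SilhouetteStack:
    frames = []
    for p in paths:
        arr = np.asarray(Image.open(Path(p)).convert("L"))
        frames.append((arr >= 128).astype(np.uint8))
    return SilhouetteStack(frames=np.stack(frames), fps=fps, meta=meta or SequenceMeta())
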