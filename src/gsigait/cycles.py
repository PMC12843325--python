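"""Gait-cycle segmentation from the ankle-separation signal.

The horizontal distance between the two ankles oscillates twice per stride
(once with the left foot leading, once with the right), so its local maxima
mark successive single-support extremes and every second maximum marks a
same-foot stride boundary.  This signal is computable from the 17-keypoint
set alone and is the standard choice for template-style gait work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.signal import find_peaks

from .geometry import ProjectedSequence
from .io import SkeletonSequence
from .topology import GSI17_INDEX

logger = logging.getLogger("gsigait")

__all__ = ["CycleSegmentation", "segment_cycles"]

_LA = GSI17_INDEX["l_ankle"]
_RA = GSI17_INDEX["r_ankle"]

MIN_CYCLE_FRAMES = 4


@dataclass
class CycleSegmentation:
    """Stride boundaries (frame indices, strictly increasing) and the
    detection signal they were found on."""

    boundaries: list
    signal: np.ndarray
    fallback: bool = False  # whole-sequence single cycle (too few maxima)

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    def cycles(self) -> list:
        return [
            (self.boundaries[i], self.boundaries[i + 1])
            for i in range(len(self.boundaries) - 1)
        ]


def ankle_separation(seq: Union[SkeletonSequence, ProjectedSequence]) -> np.ndarray:
    """|horizontal ankle separation| per frame: u on a projected sequence,
    world X on a normalized 3D sequence."""
    if isinstance(seq, ProjectedSequence):
        return np.abs(seq.frames[:, _LA, 0] - seq.frames[:, _RA, 0])
    return np.abs(seq.frames[:, _LA, 0] - seq.frames[:, _RA, 0])


def segment_cycles(
    seq: Union[SkeletonSequence, ProjectedSequence], fps: float = None
) -> CycleSegmentation:
    """Detect stride boundaries (same-foot strike to same-foot strike).

    The ankle-separation signal is mean-subtracted and smoothed with a
    moving average of window ceil(fps/10) frames, local maxima are located,
    and every second maximum becomes a boundary.  With fewer than two
    maxima a single whole-sequence cycle is returned (with a warning) so no
    sequence is ever rejected.
    """
    if fps is None:
        fps = seq.fps
    n = seq.frames.shape[0]
    if n < fps:
        logger.warning("segment_cycles: sequence shorter than 1 s (%d frames @ %g fps)", n, fps)

    raw = ankle_separation(seq)
    sig = raw - raw.mean()
    win = max(1, int(np.ceil(fps / 10.0)))
    if win > 1:
        kernel = np.ones(win) / win
        sig = np.convolve(sig, kernel, mode="same")

    # maxima at least a fifth of a second apart: twice the fastest plausible
    # step rate still separates the two per-stride maxima cleanly
    dist = max(1, int(round(0.2 * fps)))
    peaks, _ = find_peaks(sig, distance=dist)
    if len(peaks) < 2:
        logger.warning("segment_cycles: fewer than 2 maxima; whole sequence as one cycle")
        return CycleSegmentation(boundaries=[0, n], signal=sig, fallback=True)

    boundaries = [int(p) for p in peaks[::2]]  # every second maximum
    if len(boundaries) < 2:
        return CycleSegmentation(boundaries=[0, n], signal=sig, fallback=True)
    # enforce the minimum cycle length invariant
    cleaned = [boundaries[0]]
    for b in boundaries[1:]:
        if b - cleaned[-1] >= MIN_CYCLE_FRAMES:
            cleaned.append(b)
    if len(cleaned) < 2:
        return CycleSegmentation(boundaries=[0, n], signal=sig, fallback=True)
    return CycleSegmentation(boundaries=cleaned, signal=sig)
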