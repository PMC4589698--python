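"""Overlapping constant-arc-length segmentation of swimming paths.

A trajectory of arc length ``L`` is cut into windows of length ``d`` whose
start offsets advance by the *minimum path interval* ``step = d * (1 -
overlap)``.  Successive windows therefore share a fraction ``overlap`` of
their length, which makes the later per-interval classification robust to
where exactly the window boundaries fall.  Window endpoints are linearly
interpolated between tracker samples so each window's arc length tracks
``d`` closely.  Paths shorter than ``d`` (the animal swam straight to the
platform) are not segmented at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import Trajectory

__all__ = [
    "SegmentationParams",
    "Segment",
    "segment_trajectory",
    "segment_at",
    "is_direct_path",
    "cumulative_arclength",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Segment length ``d`` (cm) and overlap fraction in (0, 1).

    ``step`` is the derived minimum path interval, the resolution at which
    classes are later mapped back onto the path.
    """

    segment_length: float = 250.0
    overlap: float = 0.9

    def __post_init__(self) -> None:
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if not 0.0 < self.overlap < 1.0:
            raise ValueError("overlap must lie strictly between 0 and 1")

    @property
    def step(self) -> float:
        return self.segment_length * (1.0 - self.overlap)


@dataclass
class Segment:
    """A contiguous constant-arc-length window of one trajectory."""

    segment_id: str
    trajectory_id: str
    start_offset: float
    points: np.ndarray  # (m, 2) x/y in cm; endpoints interpolated
    actual_length: float


def cumulative_arclength(xy: np.ndarray) -> np.ndarray:
    """Cumulative arc length table, ``cum[0] == 0``, ``cum[-1] == path length``."""
    d = np.hypot(*np.diff(np.asarray(xy, dtype=float), axis=0).T)
    return np.concatenate([[0.0], np.cumsum(d)])


def is_direct_path(traj: Trajectory, params: SegmentationParams) -> bool:
    """True when the path is shorter than one segment and is left unsegmented."""
    return traj.path_length() < params.segment_length


def _slice_by_arclength(
    xy: np.ndarray, cum: np.ndarray, s0: float, s1: float
) -> np.ndarray:
    """Sub-path between arc lengths ``s0`` and ``s1`` with interpolated ends."""
    s0 = max(0.0, min(s0, cum[-1]))
    s1 = max(s0, min(s1, cum[-1]))
    i0 = int(np.searchsorted(cum, s0, side="right"))
    i1 = int(np.searchsorted(cum, s1, side="left"))

    def _at(s: float) -> np.ndarray:
        j = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(cum) - 2)
        span = cum[j + 1] - cum[j]
        f = 0.0 if span == 0 else (s - cum[j]) / span
        return xy[j] + f * (xy[j + 1] - xy[j])

    pts = [_at(s0), *xy[i0:i1], _at(s1)]
    out = np.asarray(pts, dtype=float)
    # drop zero-length duplicate edges created when s0/s1 fall on a sample
    keep = np.ones(len(out), dtype=bool)
    keep[1:] = np.hypot(*np.diff(out, axis=0).T) > 1e-12
    return out[keep]


def segment_at(traj: Trajectory, start_offset: float, d: float) -> Segment:
    """Extract the single window ``[start_offset, start_offset + d]``."""
    xy = traj.xy
    cum = cumulative_arclength(xy)
    if start_offset < -1e-9 or start_offset > cum[-1] - d + 1e-6:
        raise ValueError(
            f"start_offset {start_offset} out of range for path length {cum[-1]:.1f}"
        )
    pts = _slice_by_arclength(xy, cum, start_offset, start_offset + d)
    actual = float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))
    return Segment(
        segment_id=f"{traj.trajectory_id}:{start_offset:.1f}",
        trajectory_id=traj.trajectory_id,
        start_offset=float(start_offset),
        points=pts,
        actual_length=actual,
    )


def segment_trajectory(
    traj: Trajectory, params: SegmentationParams
) -> list[Segment]:
    """Split one trajectory into overlapping segments.

    Start offsets run ``0, step, 2*step, ...`` up to ``L - d``; if the
    residual beyond the last regular offset exceeds ``step / 2`` an extra
    segment anchored at the path end is appended so the windows always cover
    the whole path.  Returns an empty list for direct (shorter-than-``d``)
    paths; see :func:`is_direct_path`.
    """
    xy = traj.xy
    cum = cumulative_arclength(xy)
    L = float(cum[-1])
    d = params.segment_length
    step = params.step
    if L < d:
        return []
    n_regular = int(math.floor((L - d) / step + 1e-9)) + 1
    offsets = [i * step for i in range(n_regular)]
    residual = (L - d) - offsets[-1]
    if residual > step / 2.0:
        offsets.append(L - d)
    segments = []
    for off in offsets:
        pts = _slice_by_arclength(xy, cum, off, off + d)
        actual = float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))
        segments.append(
            Segment(
                segment_id=f"{traj.trajectory_id}:{len(segments):04d}",
                trajectory_id=traj.trajectory_id,
                start_offset=float(off),
                points=pts,
                actual_length=actual,
            )
        )
    return segments
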