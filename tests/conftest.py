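import numpy as np
import pytest

from swimpath import ArenaGeometry, Trajectory
from swimpath.segmentation import Segment


@pytest.fixture
def arena() -> ArenaGeometry:
    return ArenaGeometry(
        centre=(0.0, 0.0),
        arena_radius=100.0,
        platform_centre=(0.0, 50.0),
        platform_radius=6.0,
    )


def make_trajectory(xy, arena, dt=0.04, **meta) -> Trajectory:
    xy = np.asarray(xy, dtype=float)
    t = np.arange(len(xy)) * dt
    return Trajectory(points=np.column_stack([t, xy]), arena=arena, **meta)


def make_segment(points, seg_id="s0", traj_id="t0", start=0.0) -> Segment:
    points = np.asarray(points, dtype=float)
    length = float(np.sum(np.hypot(*np.diff(points, axis=0).T)))
    return Segment(
        segment_id=seg_id,
        trajectory_id=traj_id,
        start_offset=start,
        points=points,
        actual_length=length,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
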