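"""Reading and writing of trajectories, arena configuration, labels and results.

Coordinate conventions
----------------------
All positions are Cartesian centimetres with the origin at the arena centre
(the arena config may place the centre elsewhere; coordinates are used as
given and all radial quantities are measured from ``arena.centre``).  Time is
in seconds.  Downstream computation works in arc length, so the sampling rate
of the tracker is arbitrary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ArenaGeometry",
    "Trajectory",
    "TrajectoryFormatError",
    "EmptyTrajectoryError",
    "TimeOrderingError",
    "read_trajectory",
    "write_trajectory",
    "path_length",
    "read_manifest",
    "read_labels",
    "write_labels",
    "read_features",
    "write_features",
    "read_classified_path",
    "write_classified_path",
]


class TrajectoryFormatError(ValueError):
    """Raised for malformed trajectory/label/manifest files."""


class EmptyTrajectoryError(TrajectoryFormatError):
    """Raised when a trajectory file contains fewer than two samples."""


class TimeOrderingError(TrajectoryFormatError):
    """Raised when time stamps are not strictly increasing."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Geometry of the circular pool and the submerged escape platform.

    The reference setup is a 2 m diameter pool with a 12 cm diameter
    platform; all lengths in cm.
    """

    centre: tuple[float, float] = (0.0, 0.0)
    arena_radius: float = 100.0
    platform_centre: tuple[float, float] = (0.0, 50.0)
    platform_radius: float = 6.0

    def __post_init__(self) -> None:
        if self.arena_radius <= 0:
            raise ValueError("arena_radius must be positive")
        if self.platform_radius <= 0:
            raise ValueError("platform_radius must be positive")
        off = np.hypot(
            self.platform_centre[0] - self.centre[0],
            self.platform_centre[1] - self.centre[1],
        )
        if off + self.platform_radius > self.arena_radius + 1e-9:
            raise ValueError("platform must lie fully inside the arena")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ArenaGeometry":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            centre=tuple(cfg.get("centre", (0.0, 0.0))),
            arena_radius=float(cfg["arena_radius"]),
            platform_centre=tuple(cfg["platform_centre"]),
            platform_radius=float(cfg["platform_radius"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        cfg = {
            "centre": list(self.centre),
            "arena_radius": self.arena_radius,
            "platform_centre": list(self.platform_centre),
            "platform_radius": self.platform_radius,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh)


@dataclass
class Trajectory:
    """One trial's time-stamped swimming path plus metadata.

    ``points`` is an (n, 3) array of columns (t_s, x_cm, y_cm) with strictly
    increasing time.  Samples outside the arena are clamped to the wall on
    construction via :func:`read_trajectory`; ``n_clamped`` records how many.
    """

    points: np.ndarray
    arena: ArenaGeometry
    animal_id: str = ""
    group: str = ""
    day: int = 0
    trial: int = 0
    trajectory_id: str = ""
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise TrajectoryFormatError("points must be an (n, 3) array of (t, x, y)")
        if len(self.points) < 2:
            raise EmptyTrajectoryError("a trajectory needs at least two samples")
        if np.any(np.diff(self.points[:, 0]) <= 0):
            raise TimeOrderingError("time stamps must be strictly increasing")
        if not self.trajectory_id:
            self.trajectory_id = f"{self.animal_id}_d{self.day}_t{self.trial}"

    @property
    def t(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, 1:3]

    def path_length(self) -> float:
        return path_length(self)


def path_length(traj: "Trajectory | np.ndarray") -> float:
    """Total swimming path length: the sum of consecutive sample distances."""
    xy = traj.xy if isinstance(traj, Trajectory) else np.asarray(traj, dtype=float)
    return float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))


def _clamp_to_arena(
    xy: np.ndarray, arena: ArenaGeometry, tolerance: float
) -> tuple[np.ndarray, int]:
    centre = np.asarray(arena.centre)
    rel = xy - centre
    r = np.hypot(rel[:, 0], rel[:, 1])
    out = r > arena.arena_radius + tolerance
    if np.any(out):
        scale = arena.arena_radius / r[out]
        xy = xy.copy()
        xy[out] = centre + rel[out] * scale[:, None]
    return xy, int(out.sum())


def read_trajectory(
    path: str | Path,
    arena: ArenaGeometry,
    meta: Mapping | None = None,
    clamp_tolerance: float = 2.0,
) -> Trajectory:
    """Read one trial from a CSV with header ``time_s,x_cm,y_cm``.

    Points further than ``clamp_tolerance`` cm outside the wall are clamped
    radially onto the wall (a tracking glitch, not a possible rat position);
    the number of clamped samples is recorded and warned about.
    """
    df = pd.read_csv(path)
    required = ["time_s", "x_cm", "y_cm"]
    if not all(c in df.columns for c in required):
        raise TrajectoryFormatError(
            f"{path}: expected columns {required}, found {list(df.columns)}"
        )
    if len(df) < 2:
        raise EmptyTrajectoryError(f"{path}: fewer than two samples")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise TimeOrderingError(f"{path}: time stamps not strictly increasing")
    xy, n_clamped = _clamp_to_arena(
        df[["x_cm", "y_cm"]].to_numpy(dtype=float), arena, clamp_tolerance
    )
    if n_clamped:
        warnings.warn(f"{path}: clamped {n_clamped} samples to the arena wall")
    meta = dict(meta or {})
    return Trajectory(
        points=np.column_stack([t, xy]),
        arena=arena,
        animal_id=str(meta.get("animal_id", "")),
        group=str(meta.get("group", "")),
        day=int(meta.get("day", 0)),
        trial=int(meta.get("trial", 0)),
        trajectory_id=str(meta.get("id", "")),
        n_clamped=n_clamped,
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame(traj.points, columns=["time_s", "x_cm", "y_cm"]).to_csv(
        path, index=False
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Trial manifest CSV: ``id,animal_id,group,day,trial,file``."""
    df = pd.read_csv(path, dtype={"id": str, "animal_id": str, "group": str})
    required = ["id", "animal_id", "group", "day", "trial", "file"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: manifest missing columns {missing}")
    dup = df.duplicated(subset=["animal_id", "day", "trial"])
    if dup.any():
        raise TrajectoryFormatError(
            f"{path}: duplicate (animal_id, day, trial) at rows {list(df.index[dup])}"
        )
    return df


def read_labels(
    path: str | Path, known_classes: Iterable[str] | None = None
) -> dict[str, set[str]]:
    """Label CSV ``segment_id,class`` -> mapping segment_id -> set of classes.

    Multiple rows per segment express multi-label (ambiguous) segments.  An
    empty file yields an empty mapping.
    """
    from .constraints import BEHAVIOUR_CLASSES  # local import to avoid a cycle

    known = set(known_classes) if known_classes is not None else set(BEHAVIOUR_CLASSES)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    if not {"segment_id", "class"} <= set(df.columns):
        raise TrajectoryFormatError(f"{path}: expected columns segment_id,class")
    labels: dict[str, set[str]] = {}
    for row_idx, row in enumerate(df.itertuples(index=False)):
        cls = str(row[df.columns.get_loc("class")])
        if cls not in known:
            raise TrajectoryFormatError(
                f"{path}: unknown class {cls!r} at row {row_idx}"
            )
        labels.setdefault(str(row[df.columns.get_loc("segment_id")]), set()).add(cls)
    return labels


def write_labels(labels: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"segment_id": sid, "class": cls}
        for sid in sorted(labels)
        for cls in sorted(set(labels[sid]))
    ]
    pd.DataFrame(rows, columns=["segment_id", "class"]).to_csv(path, index=False)


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Feature table (index segment_id, eight named columns) -> CSV."""
    features.to_csv(path, index_label="segment_id")


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="segment_id")


def write_classified_path(paths, out: str | Path) -> None:
    """Write classified paths as CSV rows ``trajectory_id,interval_index,offset_cm,class``."""
    rows = []
    for cp in paths:
        for i, cls in enumerate(cp.classes):
            rows.append(
                {
                    "trajectory_id": cp.trajectory_id,
                    "interval_index": i,
                    "offset_cm": i * cp.interval_length,
                    "class": cls,
                }
            )
    pd.DataFrame(
        rows, columns=["trajectory_id", "interval_index", "offset_cm", "class"]
    ).to_csv(out, index=False)


def read_classified_path(path: str | Path):
    """Inverse of :func:`write_classified_path` (path_length is reconstructed
    from the interval grid, so round-trips preserve all written fields)."""
    from .path_mapping import ClassifiedPath

    df = pd.read_csv(path, dtype={"trajectory_id": str, "class": str})
    out = []
    for tid, grp in df.groupby("trajectory_id", sort=False):
        grp = grp.sort_values("interval_index")
        if len(grp) > 1:
            step = float(grp["offset_cm"].iloc[1] - grp["offset_cm"].iloc[0])
        else:
            step = float(grp["offset_cm"].iloc[0]) or 1.0
        out.append(
            ClassifiedPath(
                trajectory_id=str(tid),
                interval_length=step,
                classes=list(grp["class"]),
                path_length=step * len(grp),
                covered_length=step
                * sum(c != "undefined" for c in grp["class"]),
            )
        )
    return out
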