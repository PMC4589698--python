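"""Mapping segment classes back onto swimming paths.

The path is discretised into intervals of one minimum path interval
(= the segmentation step).  Each interval collects votes from every
overlapping classified segment: segment j of class k contributes
``w_k * exp(-d_ij^2 / (2 sigma^2))`` where ``d_ij`` is the distance of the
segment centre to the interval centre in interval units and ``sigma = 4``.
The class weight ``w_k = L_max / L_max,k`` (run lengths of consecutive
same-class segments within the trajectory) boosts transient behaviours such
as self-orienting so longer-lasting ones do not drown them out.  The
interval takes the highest-scoring class; intervals with no classified
overlapping segment stay undefined.

The *coverage* of a set of classified paths is the fraction of the total
segmented arc length whose intervals are overlapped by at least one
classified segment; it is the main quality criterion for choosing the
number of clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constraints import UNDEFINED
from .segmentation import Segment

__all__ = [
    "ClassifiedPath",
    "gaussian_kernel",
    "classify_intervals",
    "run_length_weights",
    "coverage",
    "segment_table",
    "combine_classifications",
]


@dataclass
class ClassifiedPath:
    """Per-interval behavioural class sequence for one trajectory."""

    trajectory_id: str
    interval_length: float
    classes: list[str]
    path_length: float
    covered_length: float
    direct: bool = False  # too short to segment: found the platform directly

    @property
    def coverage(self) -> float:
        return 0.0 if self.path_length == 0 else self.covered_length / self.path_length

    def __len__(self) -> int:
        return len(self.classes)


def gaussian_kernel(d: np.ndarray, sigma: float) -> np.ndarray:
    """Default interval-vote kernel, exp(-d^2 / (2 sigma^2))."""
    return np.exp(-(d * d) / (2.0 * sigma * sigma))


def _run_lengths(class_sequence: Sequence[str]) -> dict[str, int]:
    """Longest run of consecutive equal defined classes, per class."""
    runs: dict[str, int] = {}
    prev = None
    length = 0
    for cls in list(class_sequence) + [None]:
        if cls == prev:
            length += 1
        else:
            if prev is not None and prev != UNDEFINED:
                runs[prev] = max(runs.get(prev, 0), length)
            prev = cls
            length = 1
    return runs


def run_length_weights(
    segments_by_traj: Mapping[str, Sequence[Segment]],
    seg_classes: Mapping[str, str],
) -> dict[str, float]:
    """Class weights w_k = L_max / L_max,k from global run lengths.

    L_max,k is the longest run of consecutive same-class segments found in
    any trajectory of the classification; using the global scope keeps the
    weight of a class stable across trials, so a single stray misclassified
    segment in one trial is not amplified by a huge local weight.
    """
    runs: dict[str, int] = {}
    for segs in segments_by_traj.values():
        ordered = [
            seg_classes.get(s.segment_id, UNDEFINED)
            for s in sorted(segs, key=lambda s: s.start_offset)
        ]
        for cls, length in _run_lengths(ordered).items():
            runs[cls] = max(runs.get(cls, 0), length)
    if not runs:
        return {}
    l_max = max(runs.values())
    return {cls: l_max / v for cls, v in runs.items()}


def classify_intervals(
    path_length: float,
    segments: Sequence[Segment],
    seg_classes: Mapping[str, str],
    interval_length: float,
    sigma: float = 4.0,
    trajectory_id: str | None = None,
    kernel: Callable[[np.ndarray, float], np.ndarray] = gaussian_kernel,
    class_weights: Mapping[str, float] | None = None,
) -> ClassifiedPath:
    """Resolve the behavioural class of every discrete path interval.

    ``segments`` are this trajectory's segments; ``seg_classes`` maps
    segment ids to classes (``undefined`` allowed, such segments vote for no
    class but do not block coverage where classified ones overlap).  Ties
    are broken toward the class of the nearest segment centre, then toward
    the previous interval's class.  ``class_weights`` overrides the
    per-trajectory run-length weights (see :func:`run_length_weights` for
    the global variant).
    """
    n_int = max(1, math.ceil(path_length / interval_length - 1e-9))
    if trajectory_id is None:
        trajectory_id = segments[0].trajectory_id if segments else ""
    if not segments:
        return ClassifiedPath(
            trajectory_id=trajectory_id,
            interval_length=interval_length,
            classes=[UNDEFINED] * n_int,
            path_length=path_length,
            covered_length=0.0,
            direct=True,
        )

    segs = sorted(segments, key=lambda s: s.start_offset)
    ordered_classes = [seg_classes.get(s.segment_id, UNDEFINED) for s in segs]
    if class_weights is not None:
        weights = dict(class_weights)
    else:
        runs = _run_lengths(ordered_classes)
        if runs:
            l_max = max(runs.values())
            weights = {k: l_max / v for k, v in runs.items()}
        else:
            weights = {}

    starts = np.array([s.start_offset for s in segs])
    ends = starts + np.array([s.actual_length for s in segs])
    centres = (starts + ends) / 2.0
    cls_arr = np.array(ordered_classes, dtype=object)
    defined = cls_arr != UNDEFINED

    classes: list[str] = []
    covered = 0.0
    prev_class = UNDEFINED
    for i in range(n_int):
        lo, hi = i * interval_length, (i + 1) * interval_length
        arc = min(interval_length, path_length - lo)
        centre = (i + 0.5) * interval_length
        overlap = (starts < hi) & (ends > lo)
        voters = overlap & defined
        if not voters.any():
            classes.append(UNDEFINED)
            prev_class = UNDEFINED
            continue
        covered += max(arc, 0.0)
        dij = np.abs(centres[voters] - centre) / interval_length
        contrib = kernel(dij, sigma)
        vclasses = cls_arr[voters]
        scores: dict[str, float] = {}
        for cls, c in zip(vclasses, contrib):
            scores[cls] = scores.get(cls, 0.0) + c * weights.get(cls, 1.0)
        best = max(scores.values())
        tied = [cls for cls, s in scores.items() if abs(s - best) <= 1e-12 * max(1, best)]
        if len(tied) > 1:
            # nearest segment centre among tied classes, then temporal smoothness
            nearest = {
                cls: dij[vclasses == cls].min() for cls in tied
            }
            dmin = min(nearest.values())
            tied = [cls for cls in tied if nearest[cls] <= dmin + 1e-12]
            if len(tied) > 1 and prev_class in tied:
                tied = [prev_class]
        choice = sorted(tied)[0] if len(tied) > 1 else tied[0]
        classes.append(choice)
        prev_class = choice
    return ClassifiedPath(
        trajectory_id=trajectory_id,
        interval_length=interval_length,
        classes=classes,
        path_length=path_length,
        covered_length=covered,
        direct=False,
    )


def coverage(paths: Iterable[ClassifiedPath]) -> float:
    """Fraction of total segmented path length covered by classified segments.

    Direct (unsegmented) paths do not enter the ratio.
    """
    tot = cov = 0.0
    for cp in paths:
        if cp.direct:
            continue
        tot += cp.path_length
        cov += cp.covered_length
    return 0.0 if tot == 0 else cov / tot


def segment_table(
    segments: Iterable[Segment],
    seg_classes: Mapping[str, str],
    segment_length: float,
    step: float,
) -> pd.DataFrame:
    """Classified-segment table used by :func:`combine_classifications`."""
    rows = [
        {
            "segment_id": s.segment_id,
            "trajectory_id": s.trajectory_id,
            "start_offset": s.start_offset,
            "actual_length": s.actual_length,
            "class": seg_classes.get(s.segment_id, UNDEFINED),
        }
        for s in segments
    ]
    df = pd.DataFrame(
        rows,
        columns=["segment_id", "trajectory_id", "start_offset", "actual_length", "class"],
    )
    df.attrs["segment_length"] = segment_length
    df.attrs["step"] = step
    return df


def combine_classifications(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Combine two classifications of the same trajectories.

    Both must use the same segment length (overlaps may differ).  Segments
    are matched by trajectory and nearest start offset within half the finer
    step; matched pairs that disagree on a defined class become undefined,
    agreeing pairs and unmatched segments keep their class.  A segment whose
    partner is undefined keeps its own class (an undefined partner carries
    no opinion to contradict).
    """
    da, db = a.attrs.get("segment_length"), b.attrs.get("segment_length")
    if da is None or db is None or abs(da - db) > 1e-6:
        raise ValueError(
            f"classifications use different segment lengths ({da} vs {db})"
        )
    tol = min(a.attrs["step"], b.attrs["step"]) / 2.0
    a_orig, b_orig = a, b
    a = a.copy()
    b = b.copy()
    # match each side against the *original* other side, so a conflict marks
    # both partners undefined symmetrically
    for df, other in ((a, b_orig), (b, a_orig)):
        for tid, grp in df.groupby("trajectory_id", sort=False):
            cand = other[other["trajectory_id"] == tid]
            if cand.empty:
                continue
            off_o = cand["start_offset"].to_numpy()
            cls_o = cand["class"].to_numpy()
            for idx, off, cls in zip(grp.index, grp["start_offset"], grp["class"]):
                j = int(np.argmin(np.abs(off_o - off)))
                if abs(off_o[j] - off) > tol:
                    continue
                partner = cls_o[j]
                if cls != UNDEFINED and partner != UNDEFINED and partner != cls:
                    df.loc[idx, "class"] = UNDEFINED
    combined = pd.concat([a, b], ignore_index=True)
    combined.attrs["segment_length"] = da
    combined.attrs["step"] = min(a.attrs["step"], b.attrs["step"])
    return combined
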