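"""End-to-end convenience pipeline: trajectories -> classified paths.

Thin orchestration over the library modules, used by the CLI, the examples
and the verification scripts.  Nothing here does science of its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import ClassMap, ClusterModel, two_stage_cluster
from .constraints import generate_constraints, rescale_features
from .features import compute_feature_table
from .io import Trajectory
from .path_mapping import (
    ClassifiedPath,
    classify_intervals,
    coverage,
    run_length_weights,
)
from .segmentation import Segment, SegmentationParams, segment_trajectory

__all__ = ["PipelineResult", "segment_all", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced, for inspection or persistence."""

    params: SegmentationParams
    segments: dict[str, list[Segment]]  # trajectory_id -> segments ([] = direct)
    features: pd.DataFrame
    features01: pd.DataFrame
    model: ClusterModel
    class_map: ClassMap
    seg_classes: pd.Series  # segment_id -> class (or undefined)
    paths: list[ClassifiedPath]
    k1: int

    @property
    def coverage(self) -> float:
        return coverage(self.paths)


def segment_all(
    trajectories: Iterable[Trajectory], params: SegmentationParams
) -> dict[str, list[Segment]]:
    """Segment every trajectory; direct (short) paths map to empty lists."""
    return {t.trajectory_id: segment_trajectory(t, params) for t in trajectories}


def run_pipeline(
    trajectories: Sequence[Trajectory],
    labels: Mapping[str, set | str],
    params: SegmentationParams | None = None,
    k1: int | Sequence[int] | str = "auto",
    seed: int = 0,
    sigma: float = 4.0,
    d_max: float = 0.25,
    weight_scope: str = "global",
    **cluster_kwargs,
) -> PipelineResult:
    """Segment, featurise, cluster and map classes back onto the paths.

    ``k1`` may be a sequence of candidate first-stage cluster counts, in
    which case each is tried and the one with the highest coverage wins
    (coverage is the main model selection criterion).  The default
    ``"auto"`` sets one first-stage cluster per ~300 segments, the ratio
    the reference classifications used across their segmentations.
    ``weight_scope``
    chooses whether the run-length class weights are computed over the
    whole classification ("global", default) or per trajectory
    ("trajectory").
    """
    params = params or SegmentationParams()
    segments = segment_all(trajectories, params)
    flat = [s for segs in segments.values() for s in segs]
    arena = trajectories[0].arena
    features = compute_feature_table(flat, arena)
    features01 = rescale_features(features)
    constraints = generate_constraints(labels, features01, d_max=d_max)

    if isinstance(k1, str):
        if k1 != "auto":
            raise ValueError(f"unknown k1 specification {k1!r}")
        candidates = [int(np.clip(round(len(features01) / 300), 8, 100))]
    elif isinstance(k1, (int, np.integer)):
        candidates = [int(k1)]
    else:
        candidates = list(k1)
    best = None
    for k in candidates:
        model, cmap = two_stage_cluster(
            features01, int(k), constraints, labels, seed=seed, **cluster_kwargs
        )
        seg_classes = cmap.segment_classes(model)
        seg_class_dict = seg_classes.to_dict()
        weights = (
            run_length_weights(segments, seg_class_dict)
            if weight_scope == "global"
            else None
        )
        paths = []
        for traj in trajectories:
            segs = segments[traj.trajectory_id]
            paths.append(
                classify_intervals(
                    traj.path_length(),
                    segs,
                    seg_class_dict,
                    interval_length=params.step,
                    sigma=sigma,
                    trajectory_id=traj.trajectory_id,
                    class_weights=weights,
                )
            )
        cov = coverage(paths)
        if best is None or cov > best[0]:
            best = (cov, int(k), model, cmap, seg_classes, paths)

    _, k_best, model, cmap, seg_classes, paths = best
    return PipelineResult(
        params=params,
        segments=segments,
        features=features,
        features01=features01,
        model=model,
        class_map=cmap,
        seg_classes=seg_classes,
        paths=paths,
        k1=k_best,
    )
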