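"""Small plotting helpers (trajectory with classes, strategy distributions,
transition heatmap).  Convenience only; figure styling is deliberately
plain."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from .constraints import BEHAVIOUR_CLASSES, UNDEFINED
from .io import Trajectory
from .path_mapping import ClassifiedPath

_COLORS = {
    "thigmotaxis": "black",
    "incursion": "dimgray",
    "scanning": "tab:blue",
    "focused_search": "tab:green",
    "chaining_response": "olive",
    "self_orienting": "tab:purple",
    "scanning_surroundings": "tab:orange",
    "target_scanning": "tab:red",
    UNDEFINED: "lightgray",
}


def plot_trajectory(traj: Trajectory, ax=None):
    """Swimming path inside the arena with the platform zone marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    arena = traj.arena
    ax.add_patch(
        plt.Circle(arena.centre, arena.arena_radius, fill=False, color="k")
    )
    ax.add_patch(
        plt.Circle(arena.platform_centre, arena.platform_radius, color="0.6")
    )
    ax.plot(traj.xy[:, 0], traj.xy[:, 1], lw=0.8)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    return ax


def plot_class_sequence(path: ClassifiedPath, ax=None):
    """One trial as a horizontal bar of per-interval classes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 1.2))
    for i, cls in enumerate(path.classes):
        ax.axvspan(i, i + 1, color=_COLORS.get(cls, "white"))
    ax.set_xlim(0, len(path.classes))
    ax.set_yticks([])
    ax.set_xlabel("path interval")
    ax.set_title(path.trajectory_id, fontsize=8)
    return ax


def plot_strategy_lengths(per_trial: Mapping[str, Sequence[float]], ax=None):
    """Boxplots of per-trial strategy lengths (cm), one box per class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    classes = [c for c in BEHAVIOUR_CLASSES if c in per_trial]
    ax.boxplot([per_trial[c] for c in classes], tick_labels=classes)
    ax.tick_params(axis="x", rotation=45)
    ax.set_ylabel("length per trial (cm)")
    return ax
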