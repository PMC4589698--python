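"""Group-level behavioural statistics.

From classified paths: per-trial arc length spent in each strategy,
within-trial transition counts and row-normalised transition probabilities
(diagonal excluded; undefined intervals are bridged, not treated as a
class), strategy-switch counts, and a Friedman matched-block rank test for
comparing groups across trials.  The Friedman statistic is implemented with
the standard average-rank tie correction so it remains valid for two
treatments, where the common three-plus-treatment library routines refuse
to run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .constraints import BEHAVIOUR_CLASSES, UNDEFINED
from .path_mapping import ClassifiedPath

__all__ = [
    "strategy_lengths",
    "TransitionMatrix",
    "transition_matrix",
    "count_transitions",
    "friedman_test",
    "compare_groups",
]


def strategy_lengths(
    path: ClassifiedPath, classes: Sequence[str] = BEHAVIOUR_CLASSES
) -> dict[str, float]:
    """Arc length (cm) spent in each behavioural class within one trial.

    Each interval contributes one nominal interval length; undefined
    intervals are excluded (so the per-class sum plus the undefined length
    equals interval_count * interval_length exactly).
    """
    out = {cls: 0.0 for cls in classes}
    for cls in path.classes:
        if cls != UNDEFINED:
            out[cls] = out.get(cls, 0.0) + path.interval_length
    return out


def _condensed(path: ClassifiedPath) -> list[str]:
    """Defined classes with undefined intervals dropped and runs collapsed."""
    seq = [c for c in path.classes if c != UNDEFINED]
    out: list[str] = []
    for c in seq:
        if not out or out[-1] != c:
            out.append(c)
    return out


@dataclass
class TransitionMatrix:
    """Within-trial strategy transition counts and row probabilities."""

    counts: pd.DataFrame
    probabilities: pd.DataFrame

    @property
    def total_transitions(self) -> int:
        return int(self.counts.to_numpy().sum())


def transition_matrix(
    paths: Iterable[ClassifiedPath], classes: Sequence[str] = BEHAVIOUR_CLASSES
) -> TransitionMatrix:
    """Count transitions between consecutive distinct defined classes.

    Undefined intervals are skipped (bridged): T, undefined, S counts one
    T -> S transition.  Self-transitions cannot occur after run collapsing,
    so the diagonal is structurally zero.  Rows with at least one transition
    are normalised to sum to one; empty rows stay zero.
    """
    counts = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for path in paths:
        seq = _condensed(path)
        for a, b in zip(seq[:-1], seq[1:]):
            counts.loc[a, b] += 1
    row_sums = counts.sum(axis=1)
    probs = counts.div(row_sums.where(row_sums > 0, 1), axis=0).astype(float)
    return TransitionMatrix(counts=counts, probabilities=probs)


def count_transitions(path: ClassifiedPath) -> int:
    """Number of strategy changes within one trial."""
    return max(0, len(_condensed(path)) - 1)


def friedman_test(table: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Friedman chi-square test on a complete blocks x treatments table.

    Values are ranked within each block (average ranks on ties, with the
    standard tie correction); the statistic is asymptotically chi-square
    with k - 1 degrees of freedom.  A table with no rank variation at all
    returns (0.0, 1.0).
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D table with >= 2 blocks and >= 2 treatments")
    if np.any(~np.isfinite(X)):
        raise ValueError("incomplete blocks: table contains non-finite values")
    n, k = X.shape
    ranks = np.vstack([sps.rankdata(row) for row in X])
    Rj = ranks.sum(axis=0)
    num = (k - 1) * float(np.sum((Rj - n * (k + 1) / 2.0) ** 2))
    den = float(np.sum(ranks**2)) - n * k * (k + 1) ** 2 / 4.0
    if den <= 0:  # every block fully tied
        return 0.0, 1.0
    stat = num / den
    p = float(sps.chi2.sf(stat, k - 1))
    return float(stat), p


def compare_groups(
    measures: pd.DataFrame,
    blocking: str = "trial",
) -> tuple[float, float]:
    """Friedman comparison of two (or more) groups over matched trials.

    ``measures`` needs columns ``animal_id``, ``group``, ``trial`` and
    ``value``.  With ``blocking="trial"`` (default) trials are the matched
    blocks and each group's per-trial median is the treatment value.  With
    ``blocking="animal"`` the i-th animal (in id order) of each group forms
    a block and its mean over trials is the value — a matched-pair variant
    that needs equal group sizes.
    """
    required = {"animal_id", "group", "trial", "value"}
    if not required <= set(measures.columns):
        raise ValueError(f"measures needs columns {sorted(required)}")
    groups = sorted(measures["group"].unique())
    if blocking == "trial":
        table = (
            measures.groupby(["trial", "group"])["value"]
            .median()
            .unstack("group")[groups]
        )
        if table.isna().any().any():
            raise ValueError("incomplete blocks: some trial lacks a group")
        return friedman_test(table.to_numpy())
    if blocking == "animal":
        per_animal = (
            measures.groupby(["group", "animal_id"])["value"].mean().reset_index()
        )
        cols = []
        for g in groups:
            vals = per_animal[per_animal["group"] == g].sort_values("animal_id")[
                "value"
            ]
            cols.append(vals.to_numpy())
        sizes = {len(c) for c in cols}
        if len(sizes) != 1:
            raise ValueError("animal blocking requires equal group sizes")
        return friedman_test(np.column_stack(cols))
    raise ValueError(f"unknown blocking {blocking!r}")
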