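"""Behaviour classes, feature rescaling and pairwise clustering constraints.

Partial labels on segments are turned into must-link / cannot-link pairs
that guide the semi-supervised clustering.  Constraints are only generated
between labelled segments that are close in the rescaled feature space
(Euclidean distance below ``d_max``): distant pairs carry little information
for a local metric and would blow up the constraint count quadratically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "BEHAVIOUR_CLASSES",
    "UNDEFINED",
    "Constraint",
    "rescale_features",
    "single_class_labels",
    "generate_constraints",
]

#: the eight stereotyped swimming behaviours, wall-bound to platform-bound
BEHAVIOUR_CLASSES = (
    "thigmotaxis",
    "incursion",
    "scanning",
    "focused_search",
    "chaining_response",
    "self_orienting",
    "scanning_surroundings",
    "target_scanning",
)

#: sentinel for segments/intervals/clusters without an assigned class
UNDEFINED = "undefined"


@dataclass(frozen=True)
class Constraint:
    """An unordered must-link or cannot-link pair of segment ids."""

    a: str
    b: str
    kind: str  # "must_link" | "cannot_link"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("constraints must join two distinct segments")
        if self.kind not in ("must_link", "cannot_link"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("constraint weight must be positive")
        if self.b < self.a:  # canonical order so sets deduplicate pairs
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)


def rescale_features(features: pd.DataFrame) -> pd.DataFrame:
    """Min-max rescale every feature column into [0, 1].

    Constant columns map to 0.  Idempotent: rescaling twice changes nothing.
    """
    lo = features.min(axis=0)
    span = features.max(axis=0) - lo
    out = (features - lo).div(span.where(span > 0, 1.0), axis=1)
    out[span.index[span == 0]] = 0.0
    return out


def single_class_labels(labels: Mapping[str, set | str]) -> dict[str, str]:
    """Keep only unambiguous labels (multi-label segments mark ambiguity and
    are excluded from constraint generation and cluster mapping)."""
    out = {}
    for sid, cls in labels.items():
        if isinstance(cls, str):
            out[sid] = cls
        elif len(cls) == 1:
            out[sid] = next(iter(cls))
    return out


def generate_constraints(
    labels: Mapping[str, set | str],
    features01: pd.DataFrame,
    d_max: float = 0.25,
) -> set[Constraint]:
    """Pairwise constraints from labels: same class -> must-link, different
    class -> cannot-link, but only for pairs with feature distance < d_max
    (the same Euclidean distance the clustering itself uses)."""
    singles = single_class_labels(labels)
    ids = [sid for sid in features01.index if sid in singles]
    if len(ids) < 2:
        return set()
    X = features01.loc[ids].to_numpy(dtype=float)
    dist = squareform(pdist(X))
    out: set[Constraint] = set()
    iu, ju = np.triu_indices(len(ids), k=1)
    close = dist[iu, ju] < d_max
    for i, j in zip(iu[close], ju[close]):
        kind = "must_link" if singles[ids[i]] == singles[ids[j]] else "cannot_link"
        out.add(Constraint(ids[i], ids[j], kind))
    return out
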