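"""Semi-supervised constrained clustering of path segments.

Implements metric pairwise-constrained k-means (MPCK-means): k-means
extended with (i) a diagonal per-cluster learned metric, so clusters may
have different shapes and sizes, and (ii) penalty terms for violated
must-link / cannot-link constraints.  The objective minimised is

    J = sum_i  ||x_i - mu_{l_i}||^2_{A_{l_i}}  -  log det A_{l_i}
      + w * sum_{(i,j) in ML, l_i != l_j} w_ij * (||x_i-x_j||^2_{A_{l_i}}
                                                 + ||x_i-x_j||^2_{A_{l_j}}) / 2
      + w * sum_{(i,j) in CL, l_i == l_j} w_ij * (D^2_{A_{l_i}} - ||x_i-x_j||^2_{A_{l_i}})

where A_h = diag(a_h1..a_hd) and D^2_A is the metric-weighted squared
diameter of the data (per-dimension ranges), so a violated cannot-link costs
more the closer the offending pair is.  Points are (re)assigned greedily,
then centroids and metrics are updated in closed form; every step decreases
J, which the implementation asserts via the recorded objective history.

On top of the core algorithm this module provides the cluster-to-class
mapping with its label quorum, the two-stage clustering that subdivides
undefined clusters, and the 10-fold cross-validated error estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constraints import UNDEFINED, Constraint, generate_constraints, single_class_labels

__all__ = [
    "ClusterModel",
    "ClassMap",
    "CrossValidationResult",
    "initial_centroids",
    "mpck_means",
    "required_label_fraction",
    "min_labels_for_cluster",
    "map_clusters_to_classes",
    "two_stage_cluster",
    "cross_validate",
]

_METRIC_FLOOR = 1e-6
_METRIC_CAP = 1e6


@dataclass
class ClusterModel:
    """Result of one clustering run."""

    k: int
    assignments: pd.Series  # segment_id -> cluster index
    centroids: np.ndarray  # (k, d)
    metrics: np.ndarray  # (k, d) diagonal metric weights, all > 0
    objective: float
    seed: int
    stage: int = 1
    objective_history: list[float] = field(default_factory=list)
    initial_centroids: np.ndarray | None = None

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


@dataclass
class ClassMap:
    """Cluster -> behaviour class map, with per-cluster label bookkeeping.

    A cluster gets a class only if all its labels agree and there are at
    least ``min_labels[i]`` of them; otherwise it is *undefined* and its
    segments are excluded from the path mapping.
    """

    mapping: dict[int, str]
    tallies: dict[int, dict[str, int]]
    min_labels: dict[int, int]

    def class_of(self, cluster: int) -> str:
        return self.mapping.get(cluster, UNDEFINED)

    def segment_classes(self, model: ClusterModel) -> pd.Series:
        """Per-segment class implied by the model and this map."""
        return model.assignments.map(lambda c: self.class_of(int(c)))

    @property
    def defined_clusters(self) -> list[int]:
        return [c for c, cls in self.mapping.items() if cls != UNDEFINED]


def _split_constraints(
    constraints: Iterable[Constraint], index: pd.Index
) -> tuple[list[tuple[int, int, float]], list[tuple[int, int, float]]]:
    pos = {sid: i for i, sid in enumerate(index)}
    ml, cl = [], []
    for c in constraints:
        if c.a in pos and c.b in pos:
            (ml if c.kind == "must_link" else cl).append((pos[c.a], pos[c.b], c.weight))
    return ml, cl


def initial_centroids(
    X: pd.DataFrame | np.ndarray,
    k: int,
    constraints: Iterable[Constraint] = (),
    seed: int = 0,
) -> np.ndarray:
    """Farthest-point centroid seeding that respects cannot-links.

    The first centroid is a random point; each next centroid is the point
    maximising the minimum distance to the chosen ones, with points that are
    cannot-linked to an already chosen seed preferred (they must end up in a
    different cluster, so they make good seeds).
    """
    if isinstance(X, pd.DataFrame):
        x = X.to_numpy(dtype=float)
        index = X.index
    else:
        x = np.asarray(X, dtype=float)
        index = pd.RangeIndex(len(x))
    n = len(x)
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(n))]
    cl_partners: dict[int, set[int]] = {}
    for c in constraints:
        if c.kind == "cannot_link" and c.a in index and c.b in index:
            ia = index.get_loc(c.a)
            ib = index.get_loc(c.b)
            cl_partners.setdefault(ia, set()).add(ib)
            cl_partners.setdefault(ib, set()).add(ia)
    mind = np.linalg.norm(x - x[chosen[0]], axis=1)
    while len(chosen) < k:
        pref = np.zeros(n)
        linked = set().union(*(cl_partners.get(c, set()) for c in chosen)) - set(chosen)
        if linked:
            pref[list(linked)] = mind.max() + 1.0
        cand = int(np.argmax(mind + pref))
        if cand in chosen:  # all remaining points coincide with chosen seeds
            remaining = [i for i in range(n) if i not in chosen]
            cand = remaining[int(rng.integers(len(remaining)))]
        chosen.append(cand)
        mind = np.minimum(mind, np.linalg.norm(x - x[cand], axis=1))
    return x[chosen].copy()


def _objective(
    x: np.ndarray,
    assign: np.ndarray,
    centroids: np.ndarray,
    metrics: np.ndarray,
    ml: Sequence[tuple[int, int, float]],
    cl: Sequence[tuple[int, int, float]],
    range2: np.ndarray,
    w_violation: float,
) -> float:
    diff = x - centroids[assign]
    J = float(np.sum(diff * diff * metrics[assign]))
    J -= float(np.sum(np.log(metrics[assign])))
    for i, j, w in ml:
        if assign[i] != assign[j]:
            d2 = (x[i] - x[j]) ** 2
            J += w_violation * w * 0.5 * float(
                d2 @ metrics[assign[i]] + d2 @ metrics[assign[j]]
            )
    for i, j, w in cl:
        if assign[i] == assign[j]:
            d2 = (x[i] - x[j]) ** 2
            J += w_violation * w * float((range2 - d2) @ metrics[assign[i]])
    return J


def mpck_means(
    X: pd.DataFrame | np.ndarray,
    k: int,
    constraints: Iterable[Constraint] = (),
    seed: int = 0,
    w_violation: float = 10.0,
    max_iter: int = 300,
    learn_metrics: bool = True,
    init: np.ndarray | None = None,
    n_init: int = 1,
) -> ClusterModel:
    """Run MPCK-means and return the fitted :class:`ClusterModel`.

    Deterministic for fixed (X, k, constraints, seed).  With no constraints
    and ``learn_metrics=False`` the algorithm reduces exactly to Lloyd's
    k-means from the same initialisation.  ``n_init > 1`` restarts from
    different seeded initialisations and keeps the run with the lowest
    objective (standard k-means practice; restarts are seeded from ``seed``
    so the result stays deterministic).
    """
    if n_init > 1 and init is None:
        best = None
        for r in range(n_init):
            sub_seed = (seed * 2654435761 + r) % (2**31)
            m = mpck_means(
                X,
                k,
                constraints,
                seed=sub_seed,
                w_violation=w_violation,
                max_iter=max_iter,
                learn_metrics=learn_metrics,
                n_init=1,
            )
            if best is None or m.objective < best.objective:
                best = m
        best.seed = seed
        return best
    if isinstance(X, pd.DataFrame):
        index = X.index
        x = X.to_numpy(dtype=float)
    else:
        x = np.asarray(X, dtype=float)
        index = pd.RangeIndex(len(x))
    n, d = x.shape
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    constraints = list(constraints)
    ml, cl = _split_constraints(constraints, index)
    range2 = (x.max(axis=0) - x.min(axis=0)) ** 2
    rng = np.random.default_rng(seed)
    centroids = (
        init.copy() if init is not None else initial_centroids(X, k, constraints, seed)
    )
    init_centroids = centroids.copy()
    metrics = np.ones((k, d))

    # adjacency of constrained points, for the greedy assignment pass
    nbrs_ml: dict[int, list[tuple[int, float]]] = {}
    nbrs_cl: dict[int, list[tuple[int, float]]] = {}
    for i, j, w in ml:
        nbrs_ml.setdefault(i, []).append((j, w))
        nbrs_ml.setdefault(j, []).append((i, w))
    for i, j, w in cl:
        nbrs_cl.setdefault(i, []).append((j, w))
        nbrs_cl.setdefault(j, []).append((i, w))
    constrained = np.array(sorted(set(nbrs_ml) | set(nbrs_cl)), dtype=int)

    assign = np.full(n, -1, dtype=int)
    history: list[float] = []
    for _ in range(max_iter):
        # ---- E-step ------------------------------------------------------
        # base cost of putting each point in each cluster
        base = (
            ((x[:, None, :] - centroids[None, :, :]) ** 2) * metrics[None, :, :]
        ).sum(axis=2) - np.log(metrics).sum(axis=1)[None, :]
        new_assign = assign.copy()
        free = np.ones(n, dtype=bool)
        if len(constrained):
            free[constrained] = False
        new_assign[free] = np.argmin(base[free], axis=1)
        # constrained points: greedy, in seeded random order
        for i in rng.permutation(constrained):
            cost = base[i].copy()
            for j, w in nbrs_ml.get(i, ()):
                lj = new_assign[j]
                if lj < 0:
                    continue
                d2 = (x[i] - x[j]) ** 2
                pen = w_violation * w * 0.5 * (d2 @ metrics.T + d2 @ metrics[lj])
                pen[lj] = 0.0
                cost += pen
            for j, w in nbrs_cl.get(i, ()):
                lj = new_assign[j]
                if lj < 0:
                    continue
                d2 = (x[i] - x[j]) ** 2
                cost[lj] += w_violation * w * ((range2 - d2) @ metrics[lj])
            cost_i = cost
            new_assign[i] = int(np.argmin(cost_i))

        # ---- empty-cluster repair ---------------------------------------
        counts = np.bincount(new_assign, minlength=k)
        while np.any(counts == 0):
            empty = int(np.argmin(counts))
            dist_own = np.sum(
                (x - centroids[new_assign]) ** 2 * metrics[new_assign], axis=1
            )
            donor = int(np.argmax(np.where(counts[new_assign] > 1, dist_own, -np.inf)))
            centroids[empty] = x[donor]
            new_assign[donor] = empty
            counts = np.bincount(new_assign, minlength=k)

        converged = np.array_equal(new_assign, assign)
        assign = new_assign

        # ---- M-step: centroids ------------------------------------------
        for h in range(k):
            centroids[h] = x[assign == h].mean(axis=0)

        # ---- M-step: metrics --------------------------------------------
        if learn_metrics:
            counts = np.bincount(assign, minlength=k).astype(float)
            S = np.zeros((k, d))
            diff2 = (x - centroids[assign]) ** 2
            np.add.at(S, assign, diff2)
            for i, j, w in ml:
                if assign[i] != assign[j]:
                    d2 = w_violation * w * 0.5 * (x[i] - x[j]) ** 2
                    S[assign[i]] += d2
                    S[assign[j]] += d2
            for i, j, w in cl:
                if assign[i] == assign[j]:
                    S[assign[i]] += w_violation * w * (range2 - (x[i] - x[j]) ** 2)
            metrics = np.clip(
                counts[:, None] / np.maximum(S, 1e-12), _METRIC_FLOOR, _METRIC_CAP
            )

        history.append(
            _objective(x, assign, centroids, metrics, ml, cl, range2, w_violation)
        )
        if converged:
            break

    return ClusterModel(
        k=k,
        assignments=pd.Series(assign, index=index),
        centroids=centroids,
        metrics=metrics,
        objective=history[-1],
        seed=seed,
        stage=1,
        objective_history=history,
        initial_centroids=init_centroids,
    )


# --------------------------------------------------------------------------
# cluster -> class mapping


#: minimum agreeing single-class labels any cluster needs before it can be
#: mapped (chance agreement of k labels in an impure cluster decays like
#: (majority share)^k; four keeps it below ~25% even for an 70/30 mix)
EVIDENCE_FLOOR = 4


def required_label_fraction(
    n_i: int,
    gamma: float = 0.7,
    p_min: float = 0.01,
    quorum: str = "evidence",
) -> float:
    """Required labelled fraction p_i for a cluster of size n_i.

    Both strategies are non-increasing in the cluster size and floored at
    ``p_min``: small clusters must justify themselves with proportionally
    more labels, large clusters always need at least 1%.

    - ``"evidence"`` (default): absolute quorum
      m_i = max(EVIDENCE_FLOOR, ceil(gamma*(1+log10 n)), ceil(p_min*n)),
      i.e. a fixed evidence floor, a slowly growing size term, and the 1%
      proportion floor; keeps the labelling budget realistic when 5-12% of
      segments carry labels.
    - ``"geometric"``: p_i = max(p_min, gamma**(1 + log10 n)); demands far
      more labels from mid-sized clusters.
    """
    if n_i < 1:
        raise ValueError("cluster size must be >= 1")
    if quorum == "geometric":
        return max(p_min, gamma ** (1.0 + math.log10(n_i)))
    if quorum == "evidence":
        m = max(
            EVIDENCE_FLOOR,
            math.ceil(gamma * (1.0 + math.log10(n_i))),
            math.ceil(p_min * n_i),
        )
        return min(1.0, m / n_i)
    raise ValueError(f"unknown quorum strategy {quorum!r}")


def min_labels_for_cluster(
    n_i: int, gamma: float = 0.7, p_min: float = 0.01, quorum: str = "evidence"
) -> int:
    """Minimum number of labels m_i = ceil(n_i * p_i) a cluster must contain."""
    return int(math.ceil(n_i * required_label_fraction(n_i, gamma, p_min, quorum) - 1e-9))


def map_clusters_to_classes(
    model: ClusterModel,
    labels: Mapping[str, set | str],
    gamma: float = 0.7,
    p_min: float = 0.01,
    quorum: str = "evidence",
) -> ClassMap:
    """Map each cluster to the class of its labels, or to *undefined*.

    Undefined clusters are those with labels of more than one class or with
    fewer than the size-dependent minimum number of labels.
    """
    singles = single_class_labels(labels)
    mapping: dict[int, str] = {}
    tallies: dict[int, dict[str, int]] = {}
    mins: dict[int, int] = {}
    sizes = model.cluster_sizes()
    for cluster, n_i in sizes.items():
        cluster = int(cluster)
        members = model.assignments.index[model.assignments == cluster]
        tally: dict[str, int] = {}
        for sid in members:
            if sid in singles:
                tally[singles[sid]] = tally.get(singles[sid], 0) + 1
        tallies[cluster] = tally
        mins[cluster] = min_labels_for_cluster(int(n_i), gamma, p_min, quorum)
        if len(tally) == 1 and sum(tally.values()) >= mins[cluster]:
            mapping[cluster] = next(iter(tally))
        else:
            mapping[cluster] = UNDEFINED
    return ClassMap(mapping=mapping, tallies=tallies, min_labels=mins)


# --------------------------------------------------------------------------
# two-stage clustering


def two_stage_cluster(
    features01: pd.DataFrame,
    k1: int,
    constraints: Iterable[Constraint],
    labels: Mapping[str, set | str],
    seed: int = 0,
    w_violation: float = 10.0,
    gamma: float = 0.7,
    p_min: float = 0.01,
    quorum: str = "evidence",
    min_cluster_size: int = 10,
    max_iter: int = 300,
    n_init: int = 1,
) -> tuple[ClusterModel, ClassMap]:
    """Cluster in two stages and return the final model and class map.

    Stage 1 uses only cannot-link constraints (the feature space is not
    cleanly separable, so must-links between distant same-class segments
    hurt at this stage).  Every stage-1 cluster that comes out undefined and
    is large enough (>= 2 * min_cluster_size points) is then re-clustered in
    isolation with both constraint kinds, with the sub-cluster count set to
    the number of distinct label classes present plus one (at least 2).
    """
    constraints = list(constraints)
    cl_only = [c for c in constraints if c.kind == "cannot_link"]
    model1 = mpck_means(
        features01,
        k1,
        cl_only,
        seed=seed,
        w_violation=w_violation,
        max_iter=max_iter,
        n_init=n_init,
    )
    cmap1 = map_clusters_to_classes(model1, labels, gamma, p_min, quorum)
    singles = single_class_labels(labels)

    assignments = model1.assignments.copy()
    next_cluster = int(model1.assignments.max()) + 1
    for cluster in sorted(cmap1.mapping):
        if cmap1.mapping[cluster] != UNDEFINED:
            continue
        members = model1.assignments.index[model1.assignments == cluster]
        if len(members) < 2 * min_cluster_size:
            continue
        classes_present = {singles[sid] for sid in members if sid in singles}
        sub_k = max(2, len(classes_present) + 1)
        sub_k = min(sub_k, len(members) - 1)
        if sub_k < 2:
            continue
        member_set = set(members)
        sub_constraints = [
            c for c in constraints if c.a in member_set and c.b in member_set
        ]
        sub_seed = (seed * 1000003 + cluster + 1) % (2**31)
        sub_model = mpck_means(
            features01.loc[members],
            sub_k,
            sub_constraints,
            seed=sub_seed,
            w_violation=w_violation,
            max_iter=max_iter,
            n_init=n_init,
        )
        assignments.loc[members] = sub_model.assignments + next_cluster
        next_cluster += sub_k

    # re-index clusters densely and assemble the final model
    uniq = sorted(assignments.unique())
    remap = {c: i for i, c in enumerate(uniq)}
    assignments = assignments.map(remap)
    x = features01.to_numpy(dtype=float)
    kf = len(uniq)
    centroids = np.vstack(
        [x[(assignments == h).to_numpy()].mean(axis=0) for h in range(kf)]
    )
    counts = assignments.value_counts().sort_index().to_numpy().astype(float)
    S = np.zeros((kf, x.shape[1]))
    np.add.at(S, assignments.to_numpy(), (x - centroids[assignments.to_numpy()]) ** 2)
    metrics = np.clip(counts[:, None] / np.maximum(S, 1e-12), _METRIC_FLOOR, _METRIC_CAP)
    diff = x - centroids[assignments.to_numpy()]
    objective = float(
        np.sum(diff * diff * metrics[assignments.to_numpy()])
        - np.sum(np.log(metrics[assignments.to_numpy()]))
    )
    model = ClusterModel(
        k=kf,
        assignments=assignments,
        centroids=centroids,
        metrics=metrics,
        objective=objective,
        seed=seed,
        stage=2,
        objective_history=model1.objective_history,
        initial_centroids=model1.initial_centroids,
    )
    cmap = map_clusters_to_classes(model, labels, gamma, p_min, quorum)
    return model, cmap


# --------------------------------------------------------------------------
# cross-validation


@dataclass
class CrossValidationResult:
    """10-fold cross-validated error estimate of the classification."""

    error_ratio: float  # mean over folds of (#incorrect / #correct)
    error_rate: float  # conventional #incorrect / #tested-and-defined
    undefined_fraction: float  # held-out labels landing in undefined clusters
    confusion: pd.DataFrame  # true class x predicted class counts
    fold_ratios: list[float]
    fold_of: dict[str, int] | None = None  # labelled segment -> test fold


def cross_validate(
    features01: pd.DataFrame,
    k1: int,
    labels: Mapping[str, set | str],
    folds: int = 10,
    seed: int = 0,
    **cluster_kwargs,
) -> CrossValidationResult:
    """Estimate the classification error by k-fold cross-validation.

    Each fold holds out 1/``folds`` of the labelled segments: constraints
    are built from the remaining labels only, the two-stage clustering is
    run, and held-out segments are compared with their cluster's mapped
    class.  Held-out segments in undefined clusters are excluded from the
    error ratio but reported separately.  The headline number is the mean
    over folds of (#incorrect / #correct); the conventional error rate is
    also returned.
    """
    singles = single_class_labels(labels)
    ids = [sid for sid in features01.index if sid in singles]
    if len(ids) < folds:
        raise ValueError(f"need at least {folds} labelled segments, have {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fold_of = np.arange(len(ids)) % folds
    fold_assignment = {ids[i]: fold_of[r] for r, i in enumerate(order)}

    classes = sorted(set(singles.values()))
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    ratios: list[float] = []
    n_incorrect = n_correct = n_undef = 0
    for fold in range(folds):
        test_ids = [sid for sid in ids if fold_assignment[sid] == fold]
        train = {sid: singles[sid] for sid in ids if fold_assignment[sid] != fold}
        constraints = generate_constraints(train, features01)
        fold_seed = (seed * 7919 + fold) % (2**31)
        model, cmap = two_stage_cluster(
            features01, k1, constraints, train, seed=fold_seed, **cluster_kwargs
        )
        seg_classes = cmap.segment_classes(model)
        correct = incorrect = 0
        for sid in test_ids:
            pred = seg_classes.loc[sid]
            if pred == UNDEFINED:
                n_undef += 1
                continue
            if pred in confusion.columns:
                confusion.loc[singles[sid], pred] += 1
            if pred == singles[sid]:
                correct += 1
            else:
                incorrect += 1
        n_correct += correct
        n_incorrect += incorrect
        ratios.append(incorrect / max(correct, 1))
    tested = n_correct + n_incorrect
    return CrossValidationResult(
        error_ratio=float(np.mean(ratios)),
        error_rate=n_incorrect / tested if tested else 0.0,
        undefined_fraction=n_undef / len(ids),
        confusion=confusion,
        fold_ratios=ratios,
        fold_of=dict(fold_assignment),
    )
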