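"""The eight dimensionless features that describe one path segment.

Geometrical features (focus, eccentricity, maximum loop length, inner radius
variation, spread of the distance to centre) capture the shape of a segment;
positional features (median distance to centre, target proximity, central
displacement) capture where in the arena it lies.  All are dimensionless so
that segments of slightly different lengths can be mixed in one
classification.

Several features derive from the minimum-area enclosing ellipse of the
segment, computed with Khachiyan's iterative minimum-volume-ellipsoid
scheme on the convex hull of the points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .io import ArenaGeometry
from .segmentation import Segment

__all__ = [
    "Ellipse",
    "FEATURE_NAMES",
    "min_enclosing_ellipse",
    "median_distance_to_centre",
    "iqr_distance_to_centre",
    "focus",
    "target_proximity",
    "eccentricity",
    "max_loop_length",
    "inner_radius_variation",
    "central_displacement",
    "compute_features",
    "compute_feature_table",
]

FEATURE_NAMES = (
    "median_distance_centre",
    "iqr_distance_centre",
    "focus",
    "target_proximity",
    "eccentricity",
    "max_loop_length",
    "inner_radius_variation",
    "central_displacement",
)

#: semi-minor axis floor (relative to semi-major) for collinear point sets
DEGENERATE_AXIS_RATIO = 1e-3


@dataclass(frozen=True)
class Ellipse:
    """Minimum enclosing ellipse: centre, semi-axes (a >= b) and orientation."""

    centre: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float  # radians, direction of the major axis

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_major * self.semi_minor)

    def contains(self, points: np.ndarray, rtol: float = 1e-6) -> np.ndarray:
        """Boolean mask of points inside the ellipse (with relative slack)."""
        p = np.atleast_2d(points) - np.asarray(self.centre)
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = p @ np.array([c, s])
        v = p @ np.array([-s, c])
        q = (u / self.semi_major) ** 2 + (v / self.semi_minor) ** 2
        return q <= 1.0 + rtol


def _khachiyan(P: np.ndarray, tol: float, max_iter: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Core iteration: returns (centre, shape matrix A) with (p-c)' A (p-c) <= 1.

    Frank-Wolfe on the log-det problem with away (weight-decrease) steps,
    which restores linear convergence; plain increase-only steps stall at
    sublinear rates for tight tolerances.
    """
    n = len(P)
    Qt = np.column_stack([P, np.ones(n)])  # (n, 3)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Qt.T @ (Qt * u[:, None])
        # explicit symmetric 3x3 inverse: a LAPACK solve dominates the loop otherwise
        x11, x12, x13 = X[0]
        x22, x23 = X[1, 1], X[1, 2]
        x33 = X[2, 2]
        c11, c12, c13 = x22 * x33 - x23 * x23, x13 * x23 - x12 * x33, x12 * x23 - x13 * x22
        det = x11 * c11 + x12 * c12 + x13 * c13
        Xinv = (
            np.array(
                [
                    [c11, c12, c13],
                    [c12, x11 * x33 - x13 * x13, x13 * x12 - x11 * x23],
                    [c13, x13 * x12 - x11 * x23, x11 * x22 - x12 * x12],
                ]
            )
            / det
        )
        M = np.einsum("ij,jk,ik->i", Qt, Xinv, Qt)
        jp = int(np.argmax(M))
        mp = M[jp]
        support = u > 1e-12
        jm = int(np.argmin(np.where(support, M, np.inf)))
        mm = M[jm]
        if mp - 3.0 <= 3.0 * tol and 3.0 - mm <= 3.0 * tol:
            break
        if mp - 3.0 > 3.0 - mm:
            j, m = jp, mp
            stepsize = (m - 3.0) / (3.0 * (m - 1.0))
        else:
            j, m = jm, mm
            stepsize = max(
                (m - 3.0) / (3.0 * (m - 1.0)), -u[j] / (1.0 - u[j] + 1e-300)
            )
        u *= 1.0 - stepsize
        u[j] += stepsize
    c = P.T @ u
    cov = (P * u[:, None]).T @ P - np.outer(c, c)
    A = np.linalg.inv(cov) / 2.0
    return c, A


def min_enclosing_ellipse(points: np.ndarray, tol: float = 1e-4) -> Ellipse:
    """Minimum-area ellipse containing all points.

    Collinear (rank-deficient) point sets get a degenerate ellipse whose
    minor axis is floored at ``DEGENERATE_AXIS_RATIO`` times the major one so
    downstream formulas stay finite.  After the iteration the ellipse is
    inflated just enough that every input point is contained exactly.
    """
    P = np.unique(np.asarray(points, dtype=float).reshape(-1, 2), axis=0)
    if len(P) < 2:
        raise ValueError("need at least two distinct points")
    centred = P - P.mean(axis=0)
    # rank test: collinear sets cannot support a proper ellipse
    svals = np.linalg.svd(centred, compute_uv=False)
    if svals[1] <= 1e-9 * max(svals[0], 1.0):
        direction = np.linalg.svd(centred)[2][0]
        proj = centred @ direction
        a = float((proj.max() - proj.min()) / 2.0)
        mid = P.mean(axis=0) + direction * (proj.max() + proj.min()) / 2.0
        b = max(a * DEGENERATE_AXIS_RATIO, 1e-12)
        return Ellipse(tuple(mid), a, b, float(np.arctan2(direction[1], direction[0])))

    try:
        hull = P[ConvexHull(P).vertices]
    except QhullError:  # pragma: no cover - rank test normally catches this
        hull = P
    if len(hull) > 48:
        # near-circular hulls carry hundreds of vertices that slow the
        # iteration without moving the optimum; an even subsample plus the
        # final inflation step keeps the result within ~0.1% of optimal
        hull = hull[np.unique(np.linspace(0, len(hull) - 1, 48).astype(int))]
    c, A = _khachiyan(hull, tol)
    # inflate so that max_p (p-c)' A (p-c) == 1 over *all* points
    rel = P - c
    q = np.einsum("ij,jk,ik->i", rel, A, rel)
    qmax = float(q.max())
    if qmax > 1.0:
        A = A / qmax
    evals, evecs = np.linalg.eigh(A)
    axes = 1.0 / np.sqrt(evals)  # eigh: ascending evals -> axes descending
    a, b = float(axes[0]), float(axes[1])
    major = evecs[:, 0]
    if b < a * DEGENERATE_AXIS_RATIO:
        b = a * DEGENERATE_AXIS_RATIO
    return Ellipse(tuple(c), a, b, float(np.arctan2(major[1], major[0])))


def _radii(points: np.ndarray, centre) -> np.ndarray:
    rel = np.asarray(points, dtype=float) - np.asarray(centre, dtype=float)
    return np.hypot(rel[:, 0], rel[:, 1])


def median_distance_to_centre(seg: Segment, arena: ArenaGeometry) -> float:
    """Median sample distance to the arena centre over the arena radius.

    The median (not the mean) keeps a few outlying samples at the segment
    edges from dominating the value.
    """
    return float(np.median(_radii(seg.points, arena.centre)) / arena.arena_radius)


def iqr_distance_to_centre(seg: Segment, arena: ArenaGeometry) -> float:
    """(r75 - r25) / R_arena, quartiles by linear interpolation."""
    r = _radii(seg.points, arena.centre)
    q25, q75 = np.percentile(r, [25, 75])
    return float((q75 - q25) / arena.arena_radius)


def focus(seg: Segment, ellipse: Ellipse) -> float:
    """f = 1 - 4 A / (pi d^2) with A the enclosing-ellipse area and d the
    segment arc length; clipped into [0, 1] (the raw value can dip below 0
    for numerically degenerate windows).  High focus means a tightly closed
    search of a small area; a straight dash has focus ~1 only in the limit
    of zero enclosed area."""
    d = seg.actual_length
    if d <= 0:
        return 0.0
    return float(np.clip(1.0 - 4.0 * ellipse.area / (np.pi * d * d), 0.0, 1.0))


def _circle_crossing_fractions(p0, p1, centre, radius):
    """Fractions t in [0,1] where the edge p0->p1 crosses the circle."""
    dp = p1 - p0
    f = p0 - centre
    a = dp @ dp
    if a == 0:
        return []
    b = 2.0 * (f @ dp)
    c = f @ f - radius * radius
    disc = b * b - 4 * a * c
    if disc <= 0:
        return []
    sq = np.sqrt(disc)
    return [t for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)) if 0.0 < t < 1.0]


def target_proximity(seg: Segment, arena: ArenaGeometry) -> float:
    """Arc-length fraction of the segment inside the platform zone.

    The zone is the disk of radius six platform radii centred on the
    platform; edges crossing the boundary are split at the analytic
    circle-line intersection.
    """
    zone_r = 6.0 * arena.platform_radius
    centre = np.asarray(arena.platform_centre, dtype=float)
    pts = seg.points
    total = 0.0
    inside = 0.0
    for p0, p1 in zip(pts[:-1], pts[1:]):
        edge = float(np.hypot(*(p1 - p0)))
        if edge == 0:
            continue
        total += edge
        cuts = sorted([0.0, *_circle_crossing_fractions(p0, p1, centre, zone_r), 1.0])
        for t0, t1 in zip(cuts[:-1], cuts[1:]):
            mid = p0 + (t0 + t1) / 2.0 * (p1 - p0)
            if np.hypot(*(mid - centre)) <= zone_r:
                inside += (t1 - t0) * edge
    return 0.0 if total == 0 else float(inside / total)


def eccentricity(ellipse: Ellipse) -> float:
    """e = sqrt(1 - b^2/a^2): 0 for a circle, -> 1 for a line-like segment."""
    ratio = ellipse.semi_minor / ellipse.semi_major
    return float(np.sqrt(max(0.0, 1.0 - ratio * ratio)))


def max_loop_length(seg: Segment) -> float:
    """Longest self-intersecting loop's arc length over the segment length.

    Every pair of non-adjacent edges is tested for intersection; the loop
    runs along the path from the intersection point on the earlier edge to
    the intersection point on the later edge.  0 when the path never crosses
    itself.  Parallel overlapping edges are not counted as crossings.
    """
    pts = np.asarray(seg.points, dtype=float)
    d = np.diff(pts, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    keep = lengths > 1e-12
    pts = np.concatenate([pts[:-1][keep], pts[-1:]], axis=0)
    d = np.diff(pts, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    n = len(d)
    if n < 3:
        return 0.0
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    total = cum[-1]

    A = pts[:-1]  # edge starts
    # pairwise solve A_i + t d_i == A_j + u d_j
    rx = A[None, :, 0] - A[:, None, 0]
    ry = A[None, :, 1] - A[:, None, 1]
    denom = d[:, None, 0] * d[None, :, 1] - d[:, None, 1] * d[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rx * d[None, :, 1] - ry * d[None, :, 0]) / denom
        u = (rx * d[:, None, 1] - ry * d[:, None, 0]) / denom
    valid = (
        (np.abs(denom) > 1e-12)
        & (t >= 0.0)
        & (t <= 1.0)
        & (u >= 0.0)
        & (u <= 1.0)
    )
    # only pairs (i, j) with j >= i + 2: adjacent edges share a vertex
    i_idx, j_idx = np.triu_indices(n, k=2)
    mask = valid[i_idx, j_idx]
    if not mask.any():
        return 0.0
    i_idx, j_idx = i_idx[mask], j_idx[mask]
    loop = (cum[j_idx] + u[i_idx, j_idx] * lengths[j_idx]) - (
        cum[i_idx] + t[i_idx, j_idx] * lengths[i_idx]
    )
    return float(np.clip(loop.max() / total, 0.0, 1.0))


def inner_radius_variation(seg: Segment, ellipse: Ellipse) -> float:
    """IQR over median of the sample distances to the ellipse centre.

    A robust coefficient of variation of the "inner radius": exactly 0 for a
    perfect circle about the ellipse centre.  Defined as 0 when the median
    radius is 0 (all points at the centre)."""
    r = _radii(seg.points, ellipse.centre)
    med = float(np.median(r))
    if med == 0.0:
        return 0.0
    q25, q75 = np.percentile(r, [25, 75])
    return float((q75 - q25) / med)


def central_displacement(
    ellipse: Ellipse, arena: ArenaGeometry, reference: str = "arena"
) -> float:
    """Distance of the ellipse centre to the arena (or platform) centre over
    the arena radius.  The arena reference identifies paths concentric with
    the pool (chaining response); a platform reference is selectable."""
    ref = arena.centre if reference == "arena" else arena.platform_centre
    dist = float(np.hypot(ellipse.centre[0] - ref[0], ellipse.centre[1] - ref[1]))
    return dist / arena.arena_radius


def compute_features(
    seg: Segment,
    arena: ArenaGeometry,
    central_displacement_reference: str = "arena",
    ellipse_tol: float = 1e-4,
) -> dict[str, float]:
    """All eight features for one segment, keyed by :data:`FEATURE_NAMES`."""
    ell = min_enclosing_ellipse(seg.points, tol=ellipse_tol)
    return {
        "median_distance_centre": median_distance_to_centre(seg, arena),
        "iqr_distance_centre": iqr_distance_to_centre(seg, arena),
        "focus": focus(seg, ell),
        "target_proximity": target_proximity(seg, arena),
        "eccentricity": eccentricity(ell),
        "max_loop_length": max_loop_length(seg),
        "inner_radius_variation": inner_radius_variation(seg, ell),
        "central_displacement": central_displacement(
            ell, arena, central_displacement_reference
        ),
    }


def compute_feature_table(
    segments: Iterable[Segment],
    arena: ArenaGeometry,
    **kwargs,
) -> pd.DataFrame:
    """Feature table for many segments, indexed by segment_id."""
    segments = list(segments)
    ids = [seg.segment_id for seg in segments]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate segment ids in feature table input")
    rows = {seg.segment_id: compute_features(seg, arena, **kwargs) for seg in segments}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index.name = "segment_id"
    return df
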