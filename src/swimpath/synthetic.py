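"""Synthetic Morris Water Maze trajectories with known behaviour sequences.

The generator emulates tracker output for a 2 m pool with a 12 cm platform:
fixed-rate (default 25 Hz) samples of a rat swimming at roughly constant
speed for up to 90 s.  Each of the eight stereotyped behaviours is realised
as a parametric noisy curve (wall-following band, wall-anchored incursions,
diffuse central wander, small-area jitter, a platform-distance annulus
sweep, a single reorientation loop, an open pass through the platform zone,
and closed loops around the platform).  Shapes are generated densely,
blended to start exactly at the previous behaviour's end point, kept
strictly inside the arena, and then resampled at constant speed so ground
truth dwell times are exact to one sample.

These are phenomenological curves, not biophysics: they reproduce the
geometry and position of the behaviour classes well enough that the eight
features separate them, which is what the pipeline tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .constraints import BEHAVIOUR_CLASSES
from .io import ArenaGeometry, Trajectory

__all__ = [
    "BehaviourSpec",
    "SyntheticTrial",
    "GroupEffect",
    "default_arena",
    "generate_behaviour",
    "generate_trial",
    "random_behaviour_sequence",
    "generate_cohort",
    "DEFAULT_DURATIONS",
    "CONTROL_CLASS_WEIGHTS",
]

#: sampling rate of the emulated tracker (Hz)
DEFAULT_RATE = 25.0
#: swim speed of an unstressed rat (cm/s)
DEFAULT_SPEED = 25.0
#: maximum trial duration (s)
TRIAL_DURATION = 90.0
#: fraction of the arena radius paths may reach (strictly inside the wall)
_WALL_FRACTION = 0.975

DEFAULT_DURATIONS: dict[str, tuple[float, float]] = {
    "thigmotaxis": (15.0, 40.0),
    "incursion": (10.0, 25.0),
    "scanning": (10.0, 25.0),
    "focused_search": (6.0, 14.0),
    "chaining_response": (8.0, 20.0),
    "self_orienting": (3.0, 6.0),
    "scanning_surroundings": (6.0, 12.0),
    "target_scanning": (8.0, 20.0),
}

CONTROL_CLASS_WEIGHTS: dict[str, float] = {
    "thigmotaxis": 1.6,
    "incursion": 1.3,
    "scanning": 1.3,
    "focused_search": 1.0,
    "chaining_response": 0.9,
    "self_orienting": 0.9,
    "scanning_surroundings": 1.0,
    "target_scanning": 1.0,
}


def default_arena() -> ArenaGeometry:
    """2 m pool, 12 cm platform halfway between centre and wall."""
    return ArenaGeometry(
        centre=(0.0, 0.0),
        arena_radius=100.0,
        platform_centre=(0.0, 50.0),
        platform_radius=6.0,
    )


@dataclass(frozen=True)
class BehaviourSpec:
    """One bout of a stereotyped behaviour within a trial."""

    behaviour: str
    duration: float  # seconds
    speed: float = DEFAULT_SPEED  # cm/s

    def __post_init__(self) -> None:
        if self.behaviour not in BEHAVIOUR_CLASSES:
            raise ValueError(f"unknown behaviour {self.behaviour!r}")
        if self.duration <= 0 or self.speed <= 0:
            raise ValueError("duration and speed must be positive")


@dataclass
class SyntheticTrial:
    """A generated trial: trajectory plus per-sample ground-truth classes."""

    trajectory: Trajectory
    truth: np.ndarray  # per-sample behaviour class (object array of str)
    specs: list[BehaviourSpec]
    seed: int


@dataclass(frozen=True)
class GroupEffect:
    """Synthetic group contrast: stressed animals swim faster and spend more
    of the trial in the wall-bound / unstructured classes."""

    speed_factor: float = 1.15
    wall_class_factor: float = 1.8
    wall_classes: tuple[str, ...] = ("thigmotaxis", "incursion", "scanning")


def _smooth(rng: np.random.Generator, m: int, sigma: float) -> np.ndarray:
    """Unit-variance smooth noise of length m (Gaussian-filtered white noise)."""
    raw = gaussian_filter1d(rng.standard_normal(m + 1), sigma, mode="nearest")[:m]
    sd = raw.std()
    return raw / sd if sd > 1e-12 else raw


def _polar(centre: np.ndarray, r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    return centre + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _dense_shape(
    behaviour: str,
    p0: np.ndarray,
    arena: ArenaGeometry,
    rng: np.random.Generator,
    L: float,
    extent: float,
) -> np.ndarray:
    """A dense point sequence realising one behaviour, arc length ~ extent*L."""
    centre = np.asarray(arena.centre, dtype=float)
    R = arena.arena_radius
    platform = np.asarray(arena.platform_centre, dtype=float)
    rel = p0 - centre
    r0 = float(np.hypot(*rel))
    th0 = float(np.arctan2(rel[1], rel[0]))
    M = max(96, min(int(extent * L * 2.0), 60000))
    turn = rng.choice([-1.0, 1.0])
    lin = np.linspace(0.0, 1.0, M)

    if behaviour == "thigmotaxis":
        band = R * (0.92 + 0.025 * _smooth(rng, M, M / 8))
        theta = th0 + turn * lin * (extent * L / (0.90 * R)) + 0.05 * _smooth(rng, M, M / 20)
        return _polar(centre, np.clip(band, 0.87 * R, 0.97 * R), theta)

    if behaviour == "incursion":
        # repeated inward excursions from the wall: raised-cosine dips with a
        # period short enough that every segment-length window contains one
        s_arc = lin * extent * L
        period = rng.uniform(130.0, 190.0)
        depth = rng.uniform(0.25, 0.42)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        dips = 0.5 * (1.0 - np.cos(2.0 * np.pi * s_arc / period + phase))
        r = R * (0.93 - depth * dips) + 1.5 * _smooth(rng, M, M / 12)
        theta = th0 + turn * lin * (extent * L / (0.78 * R)) + 0.05 * _smooth(rng, M, M / 20)
        return _polar(centre, np.clip(r, 0.35 * R, 0.97 * R), theta)

    if behaviour == "scanning":
        # diffuse search of the central region, clearly inside the
        # platform-distance annulus swept by the chaining response
        r = R * (0.24 + 0.11 * _smooth(rng, M, M / 10))
        theta = th0 + turn * lin * (extent * L / (0.30 * R)) + 1.1 * _smooth(rng, M, M / 12)
        return _polar(centre, np.clip(r, 0.03 * R, 0.44 * R), theta)

    if behaviour == "focused_search":
        anchor = rel if r0 <= 0.80 * R else rel * (0.76 * R / r0)
        # wiggle count grows with extent so the arc length actually scales
        sig = max(3.0, M / (40.0 * extent))
        jitter = 9.0 * np.column_stack(
            [_smooth(rng, M, sig), _smooth(rng, M, sig)]
        )
        return centre + anchor + jitter

    if behaviour == "chaining_response":
        r_band = float(np.hypot(*(platform - centre)))
        r = r_band + 2.5 * _smooth(rng, M, M / 10)
        theta = th0 + turn * lin * (extent * L / r_band) + 0.03 * _smooth(rng, M, M / 20)
        return _polar(centre, r, theta)

    if behaviour == "self_orienting":
        # one full reorientation turn; long bouts wind further rather than
        # inflating the loop beyond what the arena can hold
        rho = float(np.clip(L / (2.0 * np.pi), 7.0, 0.35 * R))
        turns = max(1.05, extent * L / (2.0 * np.pi * rho))
        if r0 > 1e-9:
            loop_c = rel * max(0.0, 1.0 - rho / r0)
        else:
            phi_c = rng.uniform(0, 2 * np.pi)
            loop_c = rho * np.array([np.cos(phi_c), np.sin(phi_c)])
        phi0 = float(np.arctan2(*(rel - loop_c)[::-1]))
        phi = phi0 + turn * lin * 2.0 * np.pi * turns + 0.05 * _smooth(rng, M, M / 20)
        rr = rho * (1.0 + 0.04 * _smooth(rng, M, M / 10))
        return centre + loop_c + np.column_stack([rr * np.cos(phi), rr * np.sin(phi)])

    if behaviour == "scanning_surroundings":
        zone = 6.0 * arena.platform_radius
        off = rng.uniform(0.1, 0.45, size=2) * zone * rng.choice([-1, 1], size=2)
        w1 = platform + off
        out_dir = w1 - rel - centre
        norm = np.hypot(*out_dir)
        out_dir = out_dir / norm if norm > 1e-9 else np.array([0.0, 1.0])
        reach = max(40.0, 0.85 * extent * L - norm)
        w2 = w1 + out_dir * reach
        w2r = np.hypot(*(w2 - centre))
        if w2r > 0.90 * R:
            w2 = centre + (w2 - centre) * (0.90 * R / w2r)
        # quadratic Bezier through the platform zone plus lateral wobble
        t = lin[:, None]
        curve = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * w1 + t**2 * w2
        sig = max(3.0, M / (10.0 * extent))
        wobble = 3.0 * np.column_stack(
            [_smooth(rng, M, sig), _smooth(rng, M, sig)]
        )
        return curve + wobble

    if behaviour == "target_scanning":
        rho = 16.0 + 6.0 * _smooth(rng, M, M / 10)
        rho = np.clip(rho, 7.5, 30.0)
        phi0 = float(np.arctan2(*(rel + centre - platform)[::-1]))
        phi = phi0 + turn * lin * (extent * L / 17.0) + 0.10 * _smooth(rng, M, M / 14)
        return platform + np.column_stack([rho * np.cos(phi), rho * np.sin(phi)])

    raise ValueError(f"unknown behaviour {behaviour!r}")


def _arclength(points: np.ndarray) -> np.ndarray:
    d = np.hypot(*np.diff(points, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(d)])


def generate_behaviour(
    spec: BehaviourSpec,
    start: Sequence[float],
    arena: ArenaGeometry,
    rng: np.random.Generator | int,
    include_start: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Realise one behaviour bout from ``start``.

    Returns constant-speed samples at :data:`DEFAULT_RATE` and the matching
    ground-truth labels.  The first sample equals ``start`` when
    ``include_start`` (the caller drops it when concatenating bouts).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    p0 = np.asarray(start, dtype=float)
    centre = np.asarray(arena.centre, dtype=float)
    if np.hypot(*(p0 - centre)) >= arena.arena_radius:
        raise ValueError("start point must lie inside the arena")
    n = max(2, int(round(spec.duration * DEFAULT_RATE)))
    ds = spec.speed / DEFAULT_RATE
    L = n * ds

    extent = 1.0
    for _ in range(10):
        shape = _dense_shape(spec.behaviour, p0, arena, rng, L, extent)
        # blend so the bout starts exactly at the previous end point
        s_proxy = _arclength(shape)
        shape = shape + (p0 - shape[0]) * np.exp(-s_proxy / 25.0)[:, None]
        # keep strictly inside the wall
        relc = shape - centre
        rr = np.hypot(relc[:, 0], relc[:, 1])
        over = rr > _WALL_FRACTION * arena.arena_radius
        if np.any(over):
            relc[over] *= (_WALL_FRACTION * arena.arena_radius / rr[over])[:, None]
            shape = centre + relc
        cum = _arclength(shape)
        if cum[-1] >= L:
            break
        extent *= 1.6
    total = min(cum[-1], L + ds)
    s_samples = np.arange(n) * ds
    s_samples = np.clip(s_samples, 0.0, cum[-1])
    x = np.interp(s_samples, cum, shape[:, 0])
    y = np.interp(s_samples, cum, shape[:, 1])
    pts = np.column_stack([x, y])
    if not include_start:
        pts = pts[1:]
    labels = [spec.behaviour] * len(pts)
    return pts, labels


def generate_trial(
    specs: Sequence[BehaviourSpec],
    arena: ArenaGeometry | None = None,
    seed: int = 0,
    animal_id: str = "a01",
    group: str = "control",
    day: int = 1,
    trial: int = 1,
    start: Sequence[float] | None = None,
) -> SyntheticTrial:
    """Concatenate behaviour bouts into one continuous trial.

    The animal is released near the wall at a random angle unless ``start``
    is given.  Ground truth is aligned one class per sample.
    """
    arena = arena or default_arena()
    rng = np.random.default_rng(seed)
    if start is None:
        ang = rng.uniform(0.0, 2.0 * np.pi)
        r = 0.92 * arena.arena_radius
        start = np.asarray(arena.centre) + r * np.array([np.cos(ang), np.sin(ang)])
    pos = np.asarray(start, dtype=float)
    all_pts: list[np.ndarray] = []
    all_labels: list[str] = []
    for b, spec in enumerate(specs):
        # bouts after the first re-use their predecessor's end point, so the
        # returned block excludes the shared sample but keeps the bout's
        # sample count by asking for one extra
        if b == 0:
            pts, labels = generate_behaviour(spec, pos, arena, rng, include_start=True)
        else:
            longer = replace(spec, duration=spec.duration + 1.0 / DEFAULT_RATE)
            pts, labels = generate_behaviour(longer, pos, arena, rng, include_start=False)
            n = max(1, int(round(spec.duration * DEFAULT_RATE)))
            pts, labels = pts[:n], labels[:n]
        all_pts.append(pts)
        all_labels.extend(labels)
        pos = pts[-1]
    xy = np.vstack(all_pts)
    t = np.arange(len(xy)) / DEFAULT_RATE
    traj = Trajectory(
        points=np.column_stack([t, xy]),
        arena=arena,
        animal_id=animal_id,
        group=group,
        day=day,
        trial=trial,
    )
    return SyntheticTrial(
        trajectory=traj,
        truth=np.asarray(all_labels, dtype=object),
        specs=list(specs),
        seed=seed,
    )


def random_behaviour_sequence(
    rng: np.random.Generator,
    class_weights: Mapping[str, float] | None = None,
    speed: float = DEFAULT_SPEED,
    total_duration: float = TRIAL_DURATION,
    durations: Mapping[str, tuple[float, float]] | None = None,
) -> list[BehaviourSpec]:
    """Draw a realistic trial composition: behaviours drawn by weight (no
    immediate repeats) with class-typical dwell times, truncated to the
    trial duration."""
    weights = dict(class_weights or CONTROL_CLASS_WEIGHTS)
    durations = dict(durations or DEFAULT_DURATIONS)
    classes = list(BEHAVIOUR_CLASSES)
    w = np.array([weights.get(c, 1.0) for c in classes], dtype=float)
    specs: list[BehaviourSpec] = []
    elapsed = 0.0
    prev = None
    while elapsed < total_duration - 1e-9:
        p = w.copy()
        if prev is not None:
            p[classes.index(prev)] = 0.0
        p = p / p.sum()
        cls = classes[int(rng.choice(len(classes), p=p))]
        lo, hi = durations[cls]
        dur = float(rng.uniform(lo, hi))
        dur = min(dur, total_duration - elapsed)
        if dur < 1.5 and specs:
            specs[-1] = replace(specs[-1], duration=specs[-1].duration + dur)
            elapsed += dur
            break
        specs.append(BehaviourSpec(cls, dur, speed))
        elapsed += dur
        prev = cls
    return specs


#: classes that are salient rather than space-filling: a window containing a
#: complete bout of one of these is named after it even when most of the
#: window is context (a reorientation loop defines the window's behaviour)
TRANSIENT_CLASSES = ("self_orienting",)
#: minimum share of the window a transient bout must occupy to be salient
TRANSIENT_SALIENCE = 0.3


def _class_shares(trial: SyntheticTrial, lo: float, hi: float) -> dict[str, float]:
    xy = trial.trajectory.xy
    d = np.hypot(*np.diff(xy, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(d)])
    mask = (cum >= lo) & (cum < hi)
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[min(np.searchsorted(cum, lo), len(cum) - 1)] = True
    vals, counts = np.unique(trial.truth[mask], return_counts=True)
    total = counts.sum()
    return {str(v): c / total for v, c in zip(vals, counts)}


def majority_truth(trial: SyntheticTrial, lo: float, hi: float) -> str:
    """Most frequent ground-truth class on the arc-length window [lo, hi)."""
    shares = _class_shares(trial, lo, hi)
    return max(shares, key=shares.get)


def window_truth(trial: SyntheticTrial, lo: float, hi: float) -> str:
    """Ground-truth class of a segment-sized window.

    Like :func:`majority_truth` but salience-aware: a window containing a
    substantial complete transient bout (e.g. a full self-orienting loop) is
    named after the transient class, the way a human annotator tags the
    salient trait rather than the dominant filler.
    """
    shares = _class_shares(trial, lo, hi)
    for cls in TRANSIENT_CLASSES:
        if shares.get(cls, 0.0) >= TRANSIENT_SALIENCE:
            return cls
    return max(shares, key=shares.get)


def segment_truth(trial: SyntheticTrial, segments) -> dict[str, str]:
    """Ground-truth class per segment of this trial (salience-aware)."""
    return {
        s.segment_id: window_truth(trial, s.start_offset, s.start_offset + s.actual_length)
        for s in segments
    }


def segment_labels(
    trial: SyntheticTrial, segments, ambiguity_threshold: float = 0.25
) -> dict[str, set[str]]:
    """Ground-truth label sets per segment, emulating a human labeller.

    A segment gets every class that occupies at least ``ambiguity_threshold``
    of its window: segments straddling a behaviour change come out
    multi-label (ambiguous), exactly the situations a human annotator would
    mark with more than one label.  A window dominated by a salient
    transient bout (see :func:`window_truth`) gets that single label: the
    annotator tags the reorientation loop, not the wall-following context
    around it.
    """
    out: dict[str, set[str]] = {}
    for s in segments:
        lo, hi = s.start_offset, s.start_offset + s.actual_length
        shares = _class_shares(trial, lo, hi)
        transient = [
            cls for cls in TRANSIENT_CLASSES if shares.get(cls, 0.0) >= TRANSIENT_SALIENCE
        ]
        if transient:
            out[s.segment_id] = {transient[0]}
            continue
        chosen = {v for v, f in shares.items() if f >= ambiguity_threshold}
        if not chosen:
            chosen = {max(shares, key=shares.get)}
        out[s.segment_id] = chosen
    return out


def interval_truth(trial: SyntheticTrial, interval_length: float) -> list[str]:
    """Ground-truth class per minimum path interval of this trial."""
    from .io import path_length as _plen

    L = _plen(trial.trajectory)
    n = max(1, int(np.ceil(L / interval_length - 1e-9)))
    return [
        majority_truth(trial, i * interval_length, (i + 1) * interval_length)
        for i in range(n)
    ]


def generate_cohort(
    n_per_group: int = 8,
    n_trials: int = 6,
    seed: int = 0,
    effect: GroupEffect | None = GroupEffect(),
    arena: ArenaGeometry | None = None,
) -> tuple[pd.DataFrame, dict[str, SyntheticTrial]]:
    """Two matched groups of animals over a block of trials.

    ``effect=None`` (or a unit :class:`GroupEffect`) makes the groups
    statistically identical.  Returns the trial manifest and a mapping
    trajectory_id -> :class:`SyntheticTrial`; fully reproducible from
    ``seed``.
    """
    arena = arena or default_arena()
    effect = effect or GroupEffect(speed_factor=1.0, wall_class_factor=1.0)
    rng = np.random.default_rng(seed)
    rows = []
    trials: dict[str, SyntheticTrial] = {}
    trials_per_day = 3
    for group, prefix in (("control", "c"), ("stress", "s")):
        weights = dict(CONTROL_CLASS_WEIGHTS)
        speed = DEFAULT_SPEED
        if group == "stress":
            for cls in effect.wall_classes:
                weights[cls] = weights[cls] * effect.wall_class_factor
            speed = DEFAULT_SPEED * effect.speed_factor
        for a in range(n_per_group):
            animal_id = f"{prefix}{a + 1:02d}"
            for tr in range(1, n_trials + 1):
                specs = random_behaviour_sequence(rng, weights, speed)
                trial_seed = int(rng.integers(0, 2**31 - 1))
                st = generate_trial(
                    specs,
                    arena=arena,
                    seed=trial_seed,
                    animal_id=animal_id,
                    group=group,
                    day=(tr - 1) // trials_per_day + 1,
                    trial=tr,
                )
                trials[st.trajectory.trajectory_id] = st
                rows.append(
                    {
                        "id": st.trajectory.trajectory_id,
                        "animal_id": animal_id,
                        "group": group,
                        "day": st.trajectory.day,
                        "trial": tr,
                        "file": "",
                    }
                )
    manifest = pd.DataFrame(
        rows, columns=["id", "animal_id", "group", "day", "trial", "file"]
    )
    return manifest, trials
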