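import numpy as np
import pytest

from swimpath import ArenaGeometry
from swimpath.features import (
    FEATURE_NAMES,
    Ellipse,
    central_displacement,
    compute_features,
    eccentricity,
    focus,
    inner_radius_variation,
    iqr_distance_to_centre,
    max_loop_length,
    median_distance_to_centre,
    min_enclosing_ellipse,
    target_proximity,
)

from conftest import make_segment


class TestMinEnclosingEllipse:
    def test_symmetric_cross_gives_unit_circle(self):
        e = min_enclosing_ellipse(np.array([[1, 0], [-1, 0], [0, 1], [0, -1]]))
        assert e.centre == pytest.approx((0.0, 0.0), abs=1e-6)
        assert e.semi_major == pytest.approx(1.0, rel=1e-3)
        assert e.semi_minor == pytest.approx(1.0, rel=1e-3)

    def test_contains_all_points_and_is_minimal(self, rng):
        pts = rng.normal(size=(200, 2)) * [3.0, 1.0]
        e = min_enclosing_ellipse(pts)
        assert e.contains(pts).all()
        for a, b in [(0.99, 1.0), (1.0, 0.99)]:
            shrunk = Ellipse(e.centre, e.semi_major * a, e.semi_minor * b, e.orientation)
            assert (~shrunk.contains(pts)).sum() >= 1

    def test_collinear_points_degenerate_convention(self):
        pts = np.column_stack([np.linspace(0, 50, 6), np.zeros(6)])
        e = min_enclosing_ellipse(pts)
        assert e.semi_major == pytest.approx(25.0, rel=1e-6)
        assert e.semi_minor == pytest.approx(25.0 * 1e-3, rel=1e-6)
        assert abs(np.cos(e.orientation)) == pytest.approx(1.0, abs=1e-9)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            min_enclosing_ellipse(np.ones((5, 2)))

    def test_deterministic(self, rng):
        pts = rng.uniform(size=(50, 2))
        e1 = min_enclosing_ellipse(pts)
        e2 = min_enclosing_ellipse(pts)
        assert e1 == e2


class TestRadialFeatures:
    def test_median_distance_median_of_three(self, arena):
        seg = make_segment([(10, 0), (0, 20), (-30, 0)])
        assert median_distance_to_centre(seg, arena) == pytest.approx(0.20)

    def test_points_on_wall_give_one(self, arena):
        ang = np.linspace(0, np.pi, 20)
        seg = make_segment(np.column_stack([100 * np.cos(ang), 100 * np.sin(ang)]))
        assert median_distance_to_centre(seg, arena) == pytest.approx(1.0)

    def test_median_matches_sort_oracle(self, arena, rng):
        pts = rng.uniform(-70, 70, size=(41, 2))
        seg = make_segment(pts)
        r = np.sort(np.hypot(pts[:, 0], pts[:, 1]))
        assert median_distance_to_centre(seg, arena) == pytest.approx(
            r[20] / 100.0, abs=1e-12
        )

    def test_iqr_zero_for_constant_radius(self, arena):
        ang = np.linspace(0, 2 * np.pi, 30)
        seg = make_segment(np.column_stack([40 * np.cos(ang), 40 * np.sin(ang)]))
        assert iqr_distance_to_centre(seg, arena) == pytest.approx(0.0, abs=1e-12)

    def test_iqr_uniform_radius_grid(self, arena):
        # radii 0..100 over 101 points: q25=25, q75=75 under type-7 quartiles
        pts = np.column_stack([np.linspace(0, 100, 101), np.zeros(101)])
        seg = make_segment(pts)
        assert iqr_distance_to_centre(seg, arena) == pytest.approx(0.50)

    def test_iqr_dimensionless_under_joint_scaling(self, rng):
        pts = rng.uniform(-40, 40, size=(30, 2))
        small = ArenaGeometry(arena_radius=100.0)
        big = ArenaGeometry(arena_radius=200.0, platform_centre=(0, 100), platform_radius=12)
        assert iqr_distance_to_centre(make_segment(pts), small) == pytest.approx(
            iqr_distance_to_centre(make_segment(pts * 2), big)
        )


class TestFocusAndEccentricity:
    def test_degenerate_straight_segment_has_focus_one(self):
        seg = make_segment(np.column_stack([np.linspace(0, 50, 11), np.zeros(11)]))
        ell = min_enclosing_ellipse(seg.points)
        assert focus(seg, ell) == pytest.approx(1.0, abs=5e-3)

    def test_focus_zero_point_of_formula(self):
        # ellipse area pi*d^2/4 (a=b=d/2) makes the focus formula vanish
        seg = make_segment([(0, 0), (100, 0)])
        ell = Ellipse((50, 0), 50.0, 50.0, 0.0)
        assert focus(seg, ell) == pytest.approx(0.0, abs=1e-12)

    def test_focus_equals_formula_recomputation(self, rng):
        pts = np.cumsum(rng.normal(0, 3, size=(80, 2)), axis=0)
        seg = make_segment(pts)
        ell = min_enclosing_ellipse(pts)
        expected = np.clip(1 - 4 * ell.area / (np.pi * seg.actual_length**2), 0, 1)
        assert focus(seg, ell) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "a,b,e",
        [(2.0, 2.0, 0.0), (2.0, 1.0, np.sqrt(3) / 2), (1.0, 1e-3, np.sqrt(1 - 1e-6))],
    )
    def test_eccentricity_closed_forms(self, a, b, e):
        assert eccentricity(Ellipse((0, 0), a, b, 0.0)) == pytest.approx(e, abs=1e-12)


class TestTargetProximity:
    def test_segment_inside_zone(self, arena):
        ang = np.linspace(0, 2 * np.pi, 40)
        pts = np.column_stack([10 * np.cos(ang), 50 + 10 * np.sin(ang)])
        assert target_proximity(make_segment(pts), arena) == pytest.approx(1.0)

    def test_segment_outside_zone(self, arena):
        pts = np.column_stack([np.linspace(-60, 60, 30), np.full(30, -60.0)])
        assert target_proximity(make_segment(pts), arena) == pytest.approx(0.0)

    def test_chord_fraction_matches_analytic_intersection(self, arena):
        # horizontal line y = 50 through the zone centre: inside length equals
        # the zone diameter 2 * 36 cm
        pts = np.column_stack([np.linspace(-80, 80, 2), [50.0, 50.0]])
        seg = make_segment(pts)
        assert target_proximity(seg, arena) == pytest.approx(72.0 / 160.0, abs=1e-9)


class TestMaxLoopLength:
    def test_monotone_path_has_no_loop(self):
        seg = make_segment(np.column_stack([np.linspace(0, 80, 30), np.zeros(30)]))
        assert max_loop_length(seg) == 0.0

    def test_closed_square_is_full_loop(self):
        seg = make_segment([(0, 0), (10, 0), (10, 10), (0, 10), (0, 0)])
        assert max_loop_length(seg) == pytest.approx(1.0)

    def test_figure_eight_matches_shapely_oracle(self, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import LineString

        pts = np.cumsum(rng.normal(0, 4, size=(60, 2)), axis=0)
        seg = make_segment(pts)
        # O(n^2) oracle built on shapely's segment intersection
        edges = [LineString([pts[i], pts[i + 1]]) for i in range(len(pts) - 1)]
        lens = np.hypot(*np.diff(pts, axis=0).T)
        cum = np.concatenate([[0], np.cumsum(lens)])
        best = 0.0
        for i in range(len(edges)):
            for j in range(i + 2, len(edges)):
                inter = edges[i].intersection(edges[j])
                if inter.is_empty or inter.geom_type != "Point":
                    continue
                si = cum[i] + float(LineString([pts[i], (inter.x, inter.y)]).length)
                sj = cum[j] + float(LineString([pts[j], (inter.x, inter.y)]).length)
                best = max(best, sj - si)
        assert max_loop_length(seg) == pytest.approx(best / cum[-1], abs=1e-9)


class TestInnerRadiusVariation:
    def test_perfect_circle_is_zero(self):
        ang = np.linspace(0, 2 * np.pi, 50)
        pts = np.column_stack([30 * np.cos(ang), 30 * np.sin(ang)])
        seg = make_segment(pts)
        ell = min_enclosing_ellipse(pts)
        assert inner_radius_variation(seg, ell) == pytest.approx(0.0, abs=1e-3)

    def test_quartile_oracle_small_case(self):
        # radii 1,1,1,3 about a declared centre: IQR (type-7) = 0.5, median 1
        pts = np.array([(1, 0), (0, 1), (-1, 0), (0, -3)], dtype=float)
        seg = make_segment(pts)
        ell = Ellipse((0.0, 0.0), 3.0, 1.0, np.pi / 2)
        r = np.array([1.0, 1.0, 1.0, 3.0])
        expected = (np.percentile(r, 75) - np.percentile(r, 25)) / np.median(r)
        assert inner_radius_variation(seg, ell) == pytest.approx(expected, abs=1e-12)

    def test_all_points_at_centre_is_zero(self):
        seg = make_segment([(5.0, 5.0)] * 4)
        ell = Ellipse((5.0, 5.0), 1.0, 1.0, 0.0)
        assert inner_radius_variation(seg, ell) == 0.0


class TestCentralDisplacement:
    def test_centred_ellipse_is_zero(self, arena):
        assert central_displacement(Ellipse((0, 0), 10, 5, 0), arena) == 0.0

    def test_ellipse_on_wall_is_one(self, arena):
        assert central_displacement(Ellipse((100, 0), 10, 5, 0), arena) == pytest.approx(1.0)

    def test_matches_direct_distance(self, arena, rng):
        c = rng.uniform(-50, 50, size=2)
        ell = Ellipse(tuple(c), 10, 5, 0.3)
        assert central_displacement(ell, arena) == pytest.approx(
            np.hypot(*c) / 100.0, abs=1e-12
        )

    def test_platform_reference_switch(self, arena):
        ell = Ellipse((0, 50), 10, 5, 0)
        assert central_displacement(ell, arena, reference="platform") == 0.0
        assert central_displacement(ell, arena) == pytest.approx(0.5)


class TestInvariances:
    def _random_wiggle(self, rng, n=120):
        pts = np.cumsum(rng.normal(0, 3, size=(n, 2)), axis=0)
        pts = pts - pts.mean(axis=0) + [10.0, 20.0]
        return pts

    def test_rotation_about_arena_centre_preserves_all_features(self, arena, rng):
        pts = self._random_wiggle(rng)
        ang = 0.77
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rot_arena = ArenaGeometry(
            centre=arena.centre,
            arena_radius=arena.arena_radius,
            platform_centre=tuple(R @ np.asarray(arena.platform_centre)),
            platform_radius=arena.platform_radius,
        )
        f0 = compute_features(make_segment(pts), arena)
        f1 = compute_features(make_segment(pts @ R.T), rot_arena)
        for name in FEATURE_NAMES:
            assert f0[name] == pytest.approx(f1[name], abs=1e-6), name

    def test_translation_preserves_geometric_features(self, arena, rng):
        pts = self._random_wiggle(rng)
        seg0, seg1 = make_segment(pts), make_segment(pts + [8.0, -14.0])
        e0 = min_enclosing_ellipse(seg0.points)
        e1 = min_enclosing_ellipse(seg1.points)
        assert focus(seg0, e0) == pytest.approx(focus(seg1, e1), abs=1e-6)
        assert eccentricity(e0) == pytest.approx(eccentricity(e1), abs=1e-6)
        assert max_loop_length(seg0) == pytest.approx(max_loop_length(seg1), abs=1e-9)
        assert inner_radius_variation(seg0, e0) == pytest.approx(
            inner_radius_variation(seg1, e1), abs=1e-6
        )

    def test_features_weakly_depend_on_segment_length(self, arena, rng):
        """Median relative feature change stays small when the window length
        varies by +-10% (population regression guard, not per segment)."""
        import swimpath as sp
        from swimpath.segmentation import segment_at

        deltas = []
        for i, cls in enumerate(sp.BEHAVIOUR_CLASSES):
            st = sp.generate_trial(
                [sp.BehaviourSpec(cls, 14.0)],
                seed=100 + i,
                animal_id=f"a{i}",
            )
            traj = st.trajectory
            f0 = compute_features(segment_at(traj, 0.0, 250.0), arena)
            f1 = compute_features(segment_at(traj, 0.0, 275.0), arena)
            for name in FEATURE_NAMES:
                base = max(abs(f0[name]), 0.05)
                deltas.append(abs(f1[name] - f0[name]) / base)
        assert float(np.median(deltas)) < 0.05
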