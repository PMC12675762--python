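"""Planar primitives: Bezier evaluation, intersections, angles, rotations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spinecurve import (
    BezierCurve2D,
    CorrectionRotation,
    GeometryError,
    Line2D,
    NoIntersectionError,
    OutOfRangeError,
    bezier_eval,
    bezier_tangent,
    curve_point_at_height,
    intersect_curve_line,
    intersect_lines,
    project_to_plane,
    rotation_from_plane_angles,
    signed_angle,
)
from spinecurve.geometry import bernstein_to_power, rotate90

S2 = np.sqrt(2.0)
QUAD = BezierCurve2D([(0, 0), (1, 2), (2, 0)])


def de_casteljau(cp, t):
    """Independent recursive evaluation oracle."""
    cp = np.asarray(cp, dtype=float)
    while cp.shape[0] > 1:
        cp = (1 - t) * cp[:-1] + t * cp[1:]
    return cp[0]


class TestBezierEval:
    @pytest.mark.parametrize(
        "cps,t,expected",
        [
            ([(0, 0), (1, 1)], 0.5, (0.5, 0.5)),          # linear midpoint
            ([(0, 0), (1, 2), (2, 0)], 0.0, (0, 0)),      # endpoint interpolation
            ([(0, 0), (1, 2), (2, 0)], 1.0, (2, 0)),
            ([(0, 0), (1, 2), (2, 0)], 0.5, (1, 1)),      # 0.25 p0 + 0.5 p1 + 0.25 p2
        ],
    )
    def test_examples(self, cps, t, expected):
        assert bezier_eval(BezierCurve2D(cps), t) == pytest.approx(expected, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(GeometryError):
            bezier_eval(QUAD, 1.5)
        with pytest.raises(GeometryError):
            bezier_eval(QUAD, -0.1)

    def test_needs_two_control_points(self):
        with pytest.raises(GeometryError):
            BezierCurve2D([(0, 0)])

    def test_collinear_control_points_stay_on_line(self, rng):
        # points on the line v = 2u, arbitrary spacing
        u = np.sort(rng.uniform(-5, 5, size=5))
        curve = BezierCurve2D(np.column_stack([u, 2 * u]))
        for t in rng.uniform(0, 1, size=100):
            p = bezier_eval(curve, t)
            assert p[1] == pytest.approx(2 * p[0], abs=1e-9)

    def test_matches_de_casteljau_on_random_curves(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 9))  # degree <= 7
            cp = rng.uniform(-100, 100, size=(k, 2))
            curve = BezierCurve2D(cp)
            for t in rng.uniform(0, 1, size=10):
                np.testing.assert_allclose(
                    bezier_eval(curve, t), de_casteljau(cp, t), atol=1e-12, rtol=0
                )


class TestBezierTangent:
    def test_line_has_constant_derivative(self):
        line = BezierCurve2D([(0, 0), (2, 2)])
        for t in (0.0, 0.3, 1.0):
            assert bezier_tangent(line, t) == pytest.approx((2, 2))

    def test_endpoint_derivative_identity(self):
        # C'(0) = n (p1 - p0)
        assert bezier_tangent(QUAD, 0.0) == pytest.approx((2, 4))

    def test_symmetric_quadratic_is_horizontal_at_midpoint(self):
        assert bezier_tangent(QUAD, 0.5)[1] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_curve_raises(self):
        with pytest.raises(GeometryError):
            bezier_tangent(BezierCurve2D([(1, 1), (1, 1)]), 0.5)


class TestIntersectLines:
    def test_symmetric_crossing(self):
        a = Line2D((0, 0), (1 / S2, 1 / S2))
        b = Line2D((0, 100), (1 / S2, -1 / S2))
        pt, sa, sb = intersect_lines(a, b)
        assert pt == pytest.approx((50, 50))
        assert sa > 0 and sb > 0
        assert sa == pytest.approx(50 * S2)

    def test_parallel_returns_none(self):
        assert intersect_lines(Line2D((0, 0), (0, 1)), Line2D((5, 0), (0, 1))) is None

    def test_collinear_antiparallel_straight_spine_case(self):
        a = Line2D((0, 0), (0, 1))
        b = Line2D((0, 100), (0, -1))
        assert intersect_lines(a, b) is None


class TestCurveLineIntersection:
    def test_straight_curve_horizontal_line(self):
        curve = BezierCurve2D([(0, 0), (0, 100)])
        t, pt = intersect_curve_line(curve, Line2D((0, 25), (1, 0)), t_hint=0.3)
        assert t == pytest.approx(0.25, abs=1e-9)
        assert pt == pytest.approx((0, 25), abs=1e-9)

    def test_quadratic_against_analytic_root(self):
        # C_v(t) = 100 t^2 - 100 t + ... solves to t = 0.5 at v = 50
        curve = BezierCurve2D([(0, 0), (20, 50), (0, 100)])
        t, pt = intersect_curve_line(curve, Line2D((0, 50), (1, 0)), t_hint=0.5)
        assert pt == pytest.approx((10, 50), abs=1e-7)

    def test_line_far_from_curve(self):
        curve = BezierCurve2D([(0, 0), (0, 100)])
        with pytest.raises(NoIntersectionError):
            intersect_curve_line(curve, Line2D((50, 0), (0, 1)), t_hint=0.5)

    def test_residual_and_dense_sampling_oracle(self, rng):
        ts = np.linspace(0, 1, 10_000)
        for _ in range(20):
            k = int(rng.integers(3, 6))
            cp = rng.uniform(-50, 50, size=(k, 2))
            curve = BezierCurve2D(cp)
            p0 = bezier_eval(curve, float(rng.uniform(0.2, 0.8)))
            d = rng.normal(size=2)
            line = Line2D(p0, d / np.linalg.norm(d))
            hint = float(rng.uniform(0, 1))
            t, pt = intersect_curve_line(curve, line, t_hint=hint)
            assert abs(line.signed_distance(pt)) <= 1e-7 * max(1, np.abs(cp).max())
            dists = np.abs([line.signed_distance(bezier_eval(curve, x)) for x in ts])
            # the returned root must be a local zero the dense scan also finds
            assert np.min(np.abs(ts[np.argsort(dists)[:20]] - t)) <= 1e-4

    def test_root_selection_prefers_hint(self):
        # arched curve crosses the height v=40 twice; hint picks the branch
        curve = BezierCurve2D([(0, 0), (10, 100), (20, 0)])
        line = Line2D((0, 40), (1, 0))
        t_lo, _ = intersect_curve_line(curve, line, t_hint=0.1)
        t_hi, _ = intersect_curve_line(curve, line, t_hint=0.9)
        assert t_lo == pytest.approx(0.5 - np.sqrt(0.05), abs=1e-9)
        assert t_hi == pytest.approx(0.5 + np.sqrt(0.05), abs=1e-9)


class TestCurvePointAtHeight:
    def test_straight_vertical(self):
        t, pt = curve_point_at_height(BezierCurve2D([(0, 0), (0, 100)]), 75)
        assert t == pytest.approx(0.75, abs=1e-9)
        assert pt == pytest.approx((0, 75), abs=1e-9)

    def test_quadratic_analytic(self):
        _, pt = curve_point_at_height(BezierCurve2D([(0, 0), (20, 50), (0, 100)]), 50)
        assert pt == pytest.approx((10, 50), abs=1e-7)

    def test_out_of_range(self):
        with pytest.raises(OutOfRangeError):
            curve_point_at_height(BezierCurve2D([(0, 0), (20, 50), (0, 100)]), 150)

    def test_multiple_roots_take_most_cranial(self):
        # height profile dips back down: both 0.2-ish and later roots exist
        curve = BezierCurve2D([(0, 0), (0, 100), (0, -50)])
        t, _ = curve_point_at_height(curve, 10.0)
        assert t < 0.1


class TestSignedAngle:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 1), (0, 1), 0.0),
            ((0, 1), (1 / S2, 1 / S2), -45.0),  # clockwise from +v toward +u
            ((1 / S2, 1 / S2), (0, 1), 45.0),
            ((0, 1), (0, -1), 180.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert signed_angle(a, b) == pytest.approx(expected, abs=1e-12)
        assert abs(signed_angle(a, b)) == pytest.approx(abs(expected), abs=1e-12)

    def test_zero_vector_raises(self):
        with pytest.raises(GeometryError):
            signed_angle((0, 0), (1, 0))

    @given(
        st.floats(-np.pi, np.pi),
        st.floats(-np.pi, np.pi),
        st.floats(-np.pi, np.pi),
    )
    def test_antisymmetry_and_rotation_invariance(self, pa, pb, rot):
        a = np.array([np.cos(pa), np.sin(pa)])
        b = np.array([np.cos(pb), np.sin(pb)])
        ang = signed_angle(a, b)
        if abs(abs(ang) - 180.0) > 1e-6:
            assert signed_angle(b, a) == pytest.approx(-ang, abs=1e-9)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        assert abs(signed_angle(R @ a, R @ b)) == pytest.approx(abs(ang), abs=1e-9)


class TestProjection:
    def test_axis_mapping(self):
        p = (1.0, 2.0, 3.0)  # (left, anterior, inferior)
        assert project_to_plane(p, "sagittal") == pytest.approx((2, 3))
        assert project_to_plane(p, "coronal") == pytest.approx((1, 3))

    def test_perpendicular_normal_is_degenerate(self):
        from spinecurve import DegenerateProjectionError
        from spinecurve.geometry import project_direction

        with pytest.raises(DegenerateProjectionError):
            project_direction((1, 0, 0), "sagittal")


class TestPlaneRotations:
    def test_identity(self):
        T = rotation_from_plane_angles(CorrectionRotation(0.0, 0.0))
        np.testing.assert_allclose(T, np.eye(4), atol=1e-12)

    def test_pure_sagittal_is_rotation_about_left_axis(self):
        from scipy.spatial.transform import Rotation

        T = rotation_from_plane_angles(CorrectionRotation(90.0, 0.0))
        expected = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        np.testing.assert_allclose(T[:3, :3], expected, atol=1e-12)

    def test_rotvec_close_to_sequential_for_small_angles(self):
        from scipy.spatial.transform import Rotation

        T = rotation_from_plane_angles(CorrectionRotation(1.0, 1.0))
        seq = Rotation.from_euler("xy", [1.0, 1.0], degrees=True).as_matrix()
        diff = Rotation.from_matrix(T[:3, :3] @ seq.T).magnitude()
        assert diff <= 3e-4  # O(theta^2) for 1-degree angles

    def test_euler_variant_matches_sequential_exactly(self):
        from scipy.spatial.transform import Rotation

        T = rotation_from_plane_angles(
            CorrectionRotation(25.0, -40.0, convention="euler_xy")
        )
        seq = Rotation.from_euler("xy", [25.0, -40.0], degrees=True).as_matrix()
        np.testing.assert_allclose(T[:3, :3], seq, atol=1e-12)

    def test_orthonormal_for_random_angle_pairs(self, rng):
        for _ in range(1000):
            th = rng.uniform(-180, 180, size=2)
            R = rotation_from_plane_angles(CorrectionRotation(*th))[:3, :3]
            assert np.max(np.abs(R.T @ R - np.eye(3))) <= 1e-9


class TestLine2D:
    def test_slope_intercept_view(self):
        ln = Line2D((0, 3), (1 / S2, 1 / S2))
        assert ln.slope == pytest.approx(1.0)
        assert ln.intercept == pytest.approx(3.0)

    def test_vertical_line_flagged(self):
        ln = Line2D((2, 0), (0, 1))
        assert ln.is_vertical
        with pytest.raises(GeometryError):
            _ = ln.slope

    def test_perpendicular_is_rotation_not_reciprocal(self):
        # safe even for the vertical chord where m_p = -1/m blows up
        ln = Line2D((0, 0), (0, 1))
        perp = ln.perpendicular_through((5, 5))
        assert abs(np.dot(perp.direction, ln.direction)) < 1e-12


def test_bernstein_power_conversion_roundtrip(rng):
    for _ in range(20):
        b = rng.uniform(-10, 10, size=int(rng.integers(2, 8)))
        a = bernstein_to_power(b)
        t = rng.uniform(0, 1, size=7)
        n = b.size - 1
        direct = np.array(
            [bezier_eval(BezierCurve2D(np.column_stack([b, b])), x)[0] for x in t]
        )
        via_power = np.polynomial.polynomial.polyval(t, a)
        np.testing.assert_allclose(via_power, direct, atol=1e-10)


def test_rotate90_is_ccw():
    np.testing.assert_allclose(rotate90((1, 0)), (0, 1))
    np.testing.assert_allclose(rotate90((0, 1)), (-1, 0))
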