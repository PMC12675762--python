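"""Planar geometric primitives for spinal-curve estimation.

The spine is analysed independently in the sagittal and coronal anatomical
planes.  3-D coordinates follow the LAI scan convention (x = left,
y = anterior, z = inferior, right-handed); the in-plane coordinates are

* sagittal: (u, v) = (anterior, inferior)
* coronal:  (u, v) = (left, inferior)

so that in both planes ``v`` is the cranio-caudal "height" coordinate,
increasing caudally.  All angles are reported in degrees; the sign of an
in-plane angle is the sign of the 2-D cross product (counterclockwise
positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Literal

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateProjectionError,
    GeometryError,
    NoIntersectionError,
    OutOfRangeError,
)

PlaneTag = Literal["sagittal", "coronal"]

#: Columns of the 3-D LAI coordinate kept by each planar projection.
_PLANE_AXES: dict[str, tuple[int, int]] = {
    "sagittal": (1, 2),  # (anterior, inferior)
    "coronal": (0, 2),   # (left, inferior)
}

PARALLEL_TOL = 1e-9
ROOT_RESIDUAL_TOL = 1e-7


def _as_vec(x, dim: int) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (dim,) or not np.all(np.isfinite(v)):
        raise GeometryError(f"expected a finite {dim}-vector, got {x!r}")
    return v


def unit(v: np.ndarray, *, tol: float = 1e-12) -> np.ndarray:
    """Return ``v`` normalised to unit length."""
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n < tol:
        raise GeometryError("cannot normalise a (near-)zero vector")
    return v / n


def cross2(a: np.ndarray, b: np.ndarray) -> float:
    """Scalar 2-D cross product a_u*b_v - a_v*b_u."""
    return float(a[0] * b[1] - a[1] * b[0])


def project_to_plane(p3, plane: PlaneTag) -> np.ndarray:
    """Project a 3-D LAI point/vector into the named anatomical plane."""
    p3 = _as_vec(p3, 3)
    i, j = _PLANE_AXES[plane]
    return np.array([p3[i], p3[j]])


def project_direction(d3, plane: PlaneTag, *, tol: float = 1e-6) -> np.ndarray:
    """Project a 3-D direction and renormalise it in-plane.

    Raises
    ------
    DegenerateProjectionError
        if the direction is perpendicular to the plane (projection below
        ``tol`` in norm), in which case it carries no in-plane information.
    """
    d2 = project_to_plane(d3, plane)
    n = float(np.linalg.norm(d2))
    if n < tol:
        raise DegenerateProjectionError(
            f"direction {np.asarray(d3)} is perpendicular to the {plane} plane"
        )
    return d2 / n


def lift_to_3d(p2, plane: PlaneTag, *, other: float = 0.0) -> np.ndarray:
    """Inverse of :func:`project_to_plane`; the dropped axis is set to ``other``."""
    p2 = _as_vec(p2, 2)
    out = np.full(3, float(other))
    i, j = _PLANE_AXES[plane]
    out[i], out[j] = p2
    return out


def signed_angle(ref, target) -> float:
    """Signed in-plane angle (degrees) rotating ``ref`` onto ``target``.

    The magnitude equals arccos of the normalised dot product; the sign is
    that of the 2-D cross product (counterclockwise positive).  Result lies
    in (-180, 180].
    """
    a = _as_vec(ref, 2)
    b = _as_vec(target, 2)
    if np.linalg.norm(a) < 1e-12 or np.linalg.norm(b) < 1e-12:
        raise GeometryError("signed_angle requires two nonzero vectors")
    ang = float(np.degrees(np.arctan2(cross2(a, b), float(np.dot(a, b)))))
    if ang == -180.0:  # anti-parallel with a -0.0 cross product
        ang = 180.0
    return ang


def rotate90(d) -> np.ndarray:
    """Rotate a 2-D direction counterclockwise by 90 degrees."""
    d = _as_vec(d, 2)
    return np.array([-d[1], d[0]])


@dataclass(frozen=True)
class Line2D:
    """An in-plane line through ``point`` with unit ``direction``.

    A slope/intercept view (``m``, ``b``) is exposed for parity with the
    textbook perpendicular-line formulation, but all computations use the
    direction vector so vertical lines are handled without special cases.
    """

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", _as_vec(self.point, 2))
        object.__setattr__(self, "direction", unit(_as_vec(self.direction, 2)))

    @property
    def is_vertical(self) -> bool:
        return abs(self.direction[0]) < 1e-12

    @property
    def slope(self) -> float:
        """m = dv/du; undefined (raises) for vertical lines."""
        if self.is_vertical:
            raise GeometryError("slope undefined for a vertical line")
        return float(self.direction[1] / self.direction[0])

    @property
    def intercept(self) -> float:
        """b such that v = m*u + b; undefined for vertical lines."""
        return float(self.point[1] - self.slope * self.point[0])

    def perpendicular_through(self, p) -> "Line2D":
        return Line2D(p, rotate90(self.direction))

    def signed_distance(self, p) -> float:
        p = _as_vec(p, 2)
        return cross2(self.direction, p - self.point)


def intersect_lines(a: Line2D, b: Line2D, *, parallel_tol: float = PARALLEL_TOL):
    """Intersect two lines given as (point, unit direction) rays.

    Returns ``None`` when the directions are parallel within ``parallel_tol``
    (this includes the collinear anti-parallel straight-spine case);
    otherwise ``(point, s_a, s_b)`` where ``point = a.point + s_a*a.direction
    = b.point + s_b*b.direction``.
    """
    denom = cross2(a.direction, b.direction)
    if abs(denom) <= parallel_tol:
        return None
    dp = b.point - a.point
    s_a = cross2(dp, b.direction) / denom
    s_b = cross2(dp, a.direction) / denom
    return a.point + s_a * a.direction, float(s_a), float(s_b)


@dataclass(frozen=True)
class BezierCurve2D:
    """A Bernstein-form Bezier curve in a named anatomical plane.

    ``control_points`` is an ordered (k, 2) array, k >= 2; the curve
    interpolates the first control point at t=0 and the last at t=1.
    """

    control_points: np.ndarray
    plane: PlaneTag = "sagittal"

    def __post_init__(self):
        cp = np.asarray(self.control_points, dtype=float)
        if cp.ndim != 2 or cp.shape[0] < 2 or cp.shape[1] != 2 or not np.all(np.isfinite(cp)):
            raise GeometryError("control_points must be a finite (k>=2, 2) array")
        object.__setattr__(self, "control_points", cp)

    @property
    def degree(self) -> int:
        return self.control_points.shape[0] - 1

    def point(self, t: float) -> np.ndarray:
        return bezier_eval(self, t)

    def tangent(self, t: float) -> np.ndarray:
        return bezier_tangent(self, t)

    def to_dict(self) -> dict:
        return {"plane": self.plane, "control_points": self.control_points.tolist()}


def _check_t(t: float) -> float:
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise GeometryError(f"curve parameter t={t} outside [0, 1]")
    return t


def _bernstein_basis(n: int, t: float) -> np.ndarray:
    i = np.arange(n + 1)
    c = np.array([comb(n, k) for k in i], dtype=float)
    return c * t**i * (1.0 - t) ** (n - i)


def bezier_eval(curve: BezierCurve2D, t: float) -> np.ndarray:
    """Evaluate C(t) in Bernstein form."""
    t = _check_t(t)
    n = curve.degree
    return _bernstein_basis(n, t) @ curve.control_points


def bezier_tangent(curve: BezierCurve2D, t: float) -> np.ndarray:
    """First derivative C'(t) (the unnormalised hodograph value)."""
    t = _check_t(t)
    cp = curve.control_points
    n = curve.degree
    hodo = n * np.diff(cp, axis=0)
    if np.allclose(cp, cp[0], atol=1e-12):
        raise GeometryError("degenerate curve: all control points identical")
    if n == 1:
        return hodo[0].copy()
    return _bernstein_basis(n - 1, t) @ hodo


def bernstein_to_power(coeffs: np.ndarray) -> np.ndarray:
    """Convert scalar Bernstein coefficients to ascending power-basis coefficients."""
    b = np.asarray(coeffs, dtype=float)
    n = b.size - 1
    a = np.zeros(n + 1)
    for k in range(n + 1):
        s = sum((-1) ** (k - i) * comb(k, i) * b[i] for i in range(k + 1))
        a[k] = comb(n, k) * s
    return a


def _scalar_bezier_roots(coeffs: np.ndarray, *, tol: float = 1e-9) -> np.ndarray:
    """Real roots in [0, 1] of a scalar polynomial given in Bernstein form.

    Conversion to power basis plus ``numpy.roots`` covers the degrees arising
    here (<= number of vertebrae - 1).  Leading coefficients that are zero up
    to round-off *relative to the coefficient scale* are trimmed first - a
    spurious tiny leading term would ill-condition the companion matrix - and
    each kept root is polished by a few Newton steps, so the parameter is
    accurate to ~1e-12 even for degenerate high-degree constructions.
    """
    power = bernstein_to_power(coeffs)
    scale = float(np.max(np.abs(power)))
    if scale < 1e-12 * max(1.0, float(np.max(np.abs(coeffs))) if coeffs.size else 1.0):
        # identically zero: every t is a root; callers treat as "anywhere"
        return np.array([np.nan])
    nz = np.nonzero(np.abs(power) > 1e-12 * scale)[0]
    power = power[: nz[-1] + 1]
    if power.size == 1:
        return np.array([])
    r = np.roots(power[::-1])
    r = r[np.abs(r.imag) < 1e-6].real
    r = r[(r > -1e-6) & (r < 1.0 + 1e-6)]
    if r.size == 0:
        return r
    deriv = np.polynomial.polynomial.polyder(power)
    polished = []
    for t in np.clip(r, 0.0, 1.0):
        for _ in range(8):
            f = np.polynomial.polynomial.polyval(t, power)
            fp = np.polynomial.polynomial.polyval(t, deriv)
            if abs(fp) < 1e-14 * scale or abs(f) < 1e-15 * scale:
                break
            step = f / fp
            t = float(np.clip(t - step, 0.0, 1.0))
            if abs(step) < tol:
                break
        polished.append(t)
    return np.unique(polished)


def intersect_curve_line(
    curve: BezierCurve2D, line: Line2D, t_hint: float = 0.5
) -> tuple[float, np.ndarray]:
    """Intersection of a Bezier curve with a line.

    Solves signed-distance(C(t), line) = 0 on t in [0, 1]; among multiple
    roots returns the one nearest ``t_hint`` (the caller's chain fraction),
    preserving cranial-to-caudal ordering.

    Raises
    ------
    NoIntersectionError
        when no root lies in [0, 1]; callers decide the fallback policy.
    """
    cp = curve.control_points
    coeffs = np.array([line.signed_distance(p) for p in cp])
    roots = _scalar_bezier_roots(coeffs)
    if roots.size == 1 and np.isnan(roots[0]):
        t = float(np.clip(t_hint, 0.0, 1.0))  # curve lies on the line
        return t, bezier_eval(curve, t)
    if roots.size == 0:
        raise NoIntersectionError("line does not intersect the curve on t in [0, 1]")
    t = float(roots[np.argmin(np.abs(roots - t_hint))])
    pt = bezier_eval(curve, t)
    if abs(line.signed_distance(pt)) > ROOT_RESIDUAL_TOL * max(1.0, np.abs(cp).max()):
        raise NoIntersectionError("curve/line root residual above tolerance")
    return t, pt


def curve_point_at_height(curve: BezierCurve2D, v_target: float) -> tuple[float, np.ndarray]:
    """Most-cranial curve point whose height coordinate equals ``v_target``.

    Solves C_v(t) = v_target; if several roots exist the smallest t is
    returned (the most cranial crossing).
    """
    coeffs = curve.control_points[:, 1] - float(v_target)
    roots = _scalar_bezier_roots(coeffs)
    if roots.size == 1 and np.isnan(roots[0]):
        return 0.0, bezier_eval(curve, 0.0)
    if roots.size == 0:
        raise OutOfRangeError(f"height v={v_target} outside the curve's v-range")
    t = float(roots.min())
    return t, bezier_eval(curve, t)


def nearest_point_to_line(curve: BezierCurve2D, line: Line2D) -> tuple[float, np.ndarray]:
    """t minimising the unsigned distance from C(t) to the line.

    Graceful-degradation helper used when a perpendicular misses the curve:
    candidates are the endpoints plus the critical points of the signed
    distance polynomial.
    """
    cp = curve.control_points
    coeffs = np.array([line.signed_distance(p) for p in cp])
    power = bernstein_to_power(coeffs)
    deriv = np.polynomial.polynomial.polyder(power)
    cands = [0.0, 1.0]
    if np.any(np.abs(deriv) > 1e-14):
        r = np.polynomial.polynomial.polyroots(deriv)
        cands += [float(x.real) for x in np.atleast_1d(r) if abs(x.imag) < 1e-9 and 0 < x.real < 1]
    vals = [abs(float(np.polynomial.polynomial.polyval(t, power))) for t in cands]
    t = float(cands[int(np.argmin(vals))])
    return t, bezier_eval(curve, t)


# ---------------------------------------------------------------------------
# Rigid transforms and plane-angle rotations
# ---------------------------------------------------------------------------

RIGID_TOL = 1e-9


def validate_rigid(T, *, tol: float = 1e-6) -> np.ndarray:
    """Validate a 4x4 homogeneous rigid transform (orthonormal, det +1)."""
    from .errors import NonRigidTransformError

    T = np.asarray(T, dtype=float)
    if T.shape != (4, 4) or not np.all(np.isfinite(T)):
        raise NonRigidTransformError("expected a finite 4x4 matrix")
    R = T[:3, :3]
    if np.max(np.abs(R.T @ R - np.eye(3))) > tol:
        raise NonRigidTransformError("rotation block is not orthonormal")
    if np.linalg.det(R) < 0:
        raise NonRigidTransformError("rotation block has negative determinant")
    if np.max(np.abs(T[3] - np.array([0.0, 0.0, 0.0, 1.0]))) > tol:
        raise NonRigidTransformError("last row must be (0, 0, 0, 1)")
    return T


def make_transform(R=None, t=None) -> np.ndarray:
    T = np.eye(4)
    if R is not None:
        T[:3, :3] = np.asarray(R, dtype=float)
    if t is not None:
        T[:3, 3] = np.asarray(t, dtype=float)
    return T


def invert_rigid(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    R = T[:3, :3]
    out = np.eye(4)
    out[:3, :3] = R.T
    out[:3, 3] = -R.T @ T[:3, 3]
    return out


@dataclass(frozen=True)
class CorrectionRotation:
    """Per-vertebra 3-D correction built from the two in-plane angles.

    ``theta_s`` drives the sagittal plane (rotation about the left axis) and
    ``theta_c`` the coronal plane (rotation about the anterior axis); the
    rotation vector is r = [theta_s, theta_c, 0] in degrees, combined either
    as a single axis-angle exponential (order-free, default) or as a fixed
    x-then-y Euler sequence.  The two differ at O(theta^2).
    """

    theta_s: float
    theta_c: float
    convention: Literal["rotvec", "euler_xy"] = "rotvec"
    rotation_vector: np.ndarray = field(init=False)

    def __post_init__(self):
        for th in (self.theta_s, self.theta_c):
            if not np.isfinite(th) or abs(th) > 180.0 + 1e-9:
                raise GeometryError(f"correction angle {th} outside [-180, 180]")
        object.__setattr__(
            self, "rotation_vector", np.array([self.theta_s, self.theta_c, 0.0])
        )


def rotation_from_plane_angles(c: CorrectionRotation) -> np.ndarray:
    """4x4 rotation realising the combined per-plane correction.

    Identity when both angles are zero; a single-plane correction is an
    exact rotation about that plane's axis under either convention.
    """
    r = np.deg2rad(c.rotation_vector)
    if c.convention == "rotvec":
        R = Rotation.from_rotvec(r).as_matrix()
    elif c.convention == "euler_xy":
        R = Rotation.from_euler("xy", r[:2]).as_matrix()
    else:  # pragma: no cover - guarded by dataclass Literal
        raise GeometryError(f"unknown rotation convention {c.convention!r}")
    return make_transform(R=R)
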