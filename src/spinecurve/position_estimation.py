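"""Placement of untracked vertebrae on the estimated curve.

Two strategies transfer the CT-time chain fractions onto the curve:

* ``H`` (height): the target height of intermediate i is
  v_i = v_0 + %d_i * h_t, and its CoM is the (most cranial) curve point at
  that height.  Requires the tracked CoMs not to be level.

* ``P`` (perpendicular): base points CM_0 + u * %d_i * d_pos are laid out
  along the tracked chord; through each base point the line perpendicular to
  the chord is intersected with the curve (root nearest the fraction).
  Perpendicularity is computed by rotating the chord direction 90 degrees,
  so vertical and horizontal chords need no special-casing.

On a straight spine aligned with its chord the two strategies coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .curve_estimation import CurveEstimate
from .errors import GeometryError, NoIntersectionError, OutOfRangeError
from .geometry import Line2D, curve_point_at_height, intersect_curve_line, \
    nearest_point_to_line, rotate90, unit
from .segment import PlanarSegmentView

logger = logging.getLogger("spinecurve")


@dataclass(frozen=True)
class PositionEstimate:
    """Estimated in-plane CoMs of the intermediate vertebrae."""

    com2d: np.ndarray              # (m, 2)
    t: np.ndarray                  # (m,) curve parameters
    method: Literal["H", "P"]
    fallback: np.ndarray           # (m,) bool — perpendicular missed the curve


def estimate_positions_h(
    est: CurveEstimate, view: PlanarSegmentView, fractions
) -> PositionEstimate:
    """Height-fraction placement (strategy ``H``)."""
    fractions = np.asarray(fractions, dtype=float)
    if abs(view.h_t) <= 1e-6:
        raise GeometryError(
            "tracked CoMs are level (h_t ~ 0); height-based placement undefined"
        )
    v0 = view.com2d[0, 1]
    ts, pts = [], []
    for i, f in enumerate(fractions):
        v_target = v0 + f * view.h_t
        try:
            t, p = curve_point_at_height(est.curve, v_target)
        except OutOfRangeError as e:
            raise OutOfRangeError(
                f"intermediate vertebra {i + 1}: {e}"
            ) from None
        ts.append(t)
        pts.append(p)
    return PositionEstimate(
        com2d=np.array(pts),
        t=np.array(ts),
        method="H",
        fallback=np.zeros(len(fractions), dtype=bool),
    )


def estimate_positions_p(
    est: CurveEstimate, view: PlanarSegmentView, fractions, *, strict: bool = False
) -> PositionEstimate:
    """Perpendicular-intersection placement (strategy ``P``).

    When a perpendicular misses the curve entirely the nearest curve point is
    used instead and flagged (intraoperative streams must degrade
    gracefully); ``strict=True`` raises instead.
    """
    fractions = np.asarray(fractions, dtype=float)
    if view.d_pos <= 1e-6:
        raise GeometryError("tracked CoMs coincide in-plane (d_pos ~ 0)")
    c0 = view.com2d[0]
    u = unit(view.com2d[-1] - c0)
    perp = rotate90(u)
    ts, pts, fb = [], [], []
    for i, f in enumerate(fractions):
        base = c0 + u * f * view.d_pos
        line = Line2D(base, perp)
        try:
            t, p = intersect_curve_line(est.curve, line, t_hint=float(f))
            fell = False
        except NoIntersectionError:
            if strict:
                raise NoIntersectionError(
                    f"intermediate vertebra {i + 1}: perpendicular misses the curve"
                ) from None
            t, p = nearest_point_to_line(est.curve, line)
            fell = True
            logger.warning(
                "vertebra %d: perpendicular missed the curve; "
                "using nearest curve point (t=%.4f)", i + 1, t,
            )
        ts.append(t)
        pts.append(p)
        fb.append(fell)
    return PositionEstimate(
        com2d=np.array(pts),
        t=np.array(ts),
        method="P",
        fallback=np.array(fb, dtype=bool),
    )


def estimate_positions(
    est: CurveEstimate, view: PlanarSegmentView, fractions,
    method: str, *, strict: bool = False,
) -> PositionEstimate:
    if method == "H":
        return estimate_positions_h(est, view, fractions)
    if method == "P":
        return estimate_positions_p(est, view, fractions, strict=strict)
    raise GeometryError(f"unknown position-estimation method {method!r}")
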