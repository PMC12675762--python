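"""Bezier control-point construction from the two tracked vertebrae.

Two constructions estimate the in-plane spinal curve between the projected
CoMs of the tracked pair:

* ``EN`` (endplate normals): if the ray from CM_0 along the inferior-endplate
  normal of the superior tracked vertebra and the ray from CM_{n-1} along the
  superior-endplate normal of the inferior tracked vertebra intersect (both
  ray parameters positive), the intersection is the single interior control
  point of a quadratic.  Otherwise four equally spaced control points are
  used, offsetting each endpoint by d_pos/4 along its normal.

* ``ENIP`` (endplate normals + initial positions): one control point per
  vertebra.  Intermediate control points are laid out along the endpoint
  normals at the CT-time chain fractions of the total tracked distance, from
  whichever tracked endpoint the vertebra is closer to (by vertebra count);
  with an odd number of intermediates the middle vertebra's control point is
  the midpoint of the two candidates.

Both constructions interpolate the projected tracked CoMs exactly.  With
four vertebrae in the segment the two curves nearly coincide; they diverge
only for longer spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .errors import ValidationError
from .geometry import BezierCurve2D, Line2D, intersect_lines
from .segment import PlanarSegmentView

#: Minimum positive ray parameter for the normals to count as intersecting.
_RAY_EPS = 1e-9


@dataclass(frozen=True)
class CurveEstimate:
    """An estimated in-plane curve plus provenance of its control points."""

    curve: BezierCurve2D
    method: Literal["EN", "ENIP"]
    case: Optional[Literal["INTERSECTING", "NON_INTERSECTING"]] = None
    provenance: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "case": self.case,
            "provenance": list(self.provenance),
            **self.curve.to_dict(),
        }


def estimate_curve_en(view: PlanarSegmentView) -> CurveEstimate:
    """Curve estimation from the tracked endplate normals alone."""
    c0 = view.com2d[0]
    c1 = view.com2d[-1]
    d0 = view.n_inf2d[0]      # caudal normal of the superior tracked vertebra
    d1 = view.n_sup2d[-1]     # cranial normal of the inferior tracked vertebra
    hit = intersect_lines(Line2D(c0, d0), Line2D(c1, d1))
    if hit is not None:
        pt, s0, s1 = hit
        if s0 > _RAY_EPS and s1 > _RAY_EPS:
            curve = BezierCurve2D(np.array([c0, pt, c1]), plane=view.plane)
            return CurveEstimate(
                curve=curve,
                method="EN",
                case="INTERSECTING",
                provenance=("CM_0", "normals intersection", "CM_last"),
            )
    off = view.d_pos / 4.0
    cps = np.array([c0, c0 + d0 * off, c1 + d1 * off, c1])
    return CurveEstimate(
        curve=BezierCurve2D(cps, plane=view.plane),
        method="EN",
        case="NON_INTERSECTING",
        provenance=("CM_0", "CM_0 + n_I0*d_pos/4", "CM_last + n_S*d_pos/4", "CM_last"),
    )


def estimate_curve_enip(view: PlanarSegmentView, fractions) -> CurveEstimate:
    """Curve estimation from endplate normals and CT-time vertebra spacing."""
    n = view.com2d.shape[0]
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (n - 2,):
        raise ValidationError(
            f"need {n - 2} chain fractions for {n} vertebrae, got {fractions.size}"
        )
    c0 = view.com2d[0]
    c1 = view.com2d[-1]
    d0 = view.n_inf2d[0]
    d1 = view.n_sup2d[-1]
    cps = [c0]
    prov = ["CM_0"]
    for i in range(1, n - 1):
        f = fractions[i - 1]
        from_sup = c0 + d0 * f * view.d_pos
        from_inf = c1 + d1 * (1.0 - f) * view.d_pos
        if i < n - 1 - i:
            cps.append(from_sup)
            prov.append(f"CM_0 + n_I0*{f:.4g}*d_pos")
        elif i > n - 1 - i:
            cps.append(from_inf)
            prov.append(f"CM_last + n_S*(1-{f:.4g})*d_pos")
        else:
            cps.append(0.5 * (from_sup + from_inf))
            prov.append("midpoint of superior/inferior candidates")
    cps.append(c1)
    prov.append("CM_last")
    return CurveEstimate(
        curve=BezierCurve2D(np.array(cps), plane=view.plane),
        method="ENIP",
        provenance=tuple(prov),
    )


def estimate_curve(view: PlanarSegmentView, method: str, fractions=None) -> CurveEstimate:
    if method == "EN":
        return estimate_curve_en(view)
    if method == "ENIP":
        if fractions is None:
            raise ValidationError("ENIP requires the CT-time chain fractions")
        return estimate_curve_enip(view, fractions)
    raise ValidationError(f"unknown curve-estimation method {method!r}")
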