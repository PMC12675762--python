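"""Orientation correction of intermediate vertebrae from curve tangents.

The curve's first derivative gives the local tangent at each estimated CoM.
Two references define the correction angle in each plane:

* ``STV``: the tangent at the superior tracked vertebra's CoM (t at 0); the
  intermediate vertebra is turned by the curve's local deviation from it.
* ``IVN``: the vertebra's own intermediate endplate vector
  v_i = (n_inf - n_sup) / 2 (projected, registration-time); the correction
  rotates the vertebra so v_i becomes parallel to the local tangent.

The magnitude of each angle is arccos of the normalised dot product; its
sign comes from the 2-D cross product (a rotation needs a direction, and the
cross-product sign is the orientation-consistent choice).  The sagittal and
coronal angles are then combined into one 3-D rotation and composed onto the
vertebra's registration-time orientation, so repeated updates never
accumulate drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .curve_estimation import CurveEstimate
from .errors import GeometryError, ValidationError
from .geometry import (
    CorrectionRotation,
    bezier_tangent,
    lift_to_3d,
    rotation_from_plane_angles,
    signed_angle,
)
from .position_estimation import PositionEstimate
from .segment import PlanarSegmentView, SpineSegment

logger = logging.getLogger("spinecurve")

#: Height-reconciliation discrepancies above this many mm are logged.
_HEIGHT_LOG_TOL = 1e-6


@dataclass(frozen=True)
class OrientationCorrection:
    """Correction angle of one intermediate vertebra in one plane."""

    index: int                       # vertebra index within the segment
    theta_deg: float                 # signed in-plane angle (CCW positive)
    tangent: np.ndarray              # local curve tangent t_i
    reference: np.ndarray            # t_0 (STV) or v_i (IVN)
    method: Literal["STV", "IVN"]
    plane: str


def correct_orientation_stv(
    est: CurveEstimate, pos: PositionEstimate, indices
) -> list[OrientationCorrection]:
    """Angles aligning each local tangent with the superior tangent t_0."""
    t0 = bezier_tangent(est.curve, 0.0)
    out = []
    for idx, t_par in zip(indices, pos.t):
        ti = bezier_tangent(est.curve, float(t_par))
        theta = signed_angle(t0, ti)
        out.append(
            OrientationCorrection(
                index=int(idx), theta_deg=theta, tangent=ti,
                reference=t0, method="STV", plane=est.curve.plane,
            )
        )
    return out


def correct_orientation_ivn(
    est: CurveEstimate, pos: PositionEstimate, view: PlanarSegmentView, indices
) -> list[OrientationCorrection]:
    """Angles aligning each intermediate endplate vector v_i with its tangent."""
    out = []
    for idx, t_par in zip(indices, pos.t):
        v_i = 0.5 * (view.n_inf2d[idx] - view.n_sup2d[idx])
        if np.linalg.norm(v_i) < 1e-9:
            raise GeometryError(
                f"vertebra index {idx}: endplate normals are parallel and "
                "same-signed; intermediate vector is zero"
            )
        ti = bezier_tangent(est.curve, float(t_par))
        theta = signed_angle(v_i, ti)
        out.append(
            OrientationCorrection(
                index=int(idx), theta_deg=theta, tangent=ti,
                reference=v_i, method="IVN", plane=est.curve.plane,
            )
        )
    return out


def correct_orientation(
    est: CurveEstimate, pos: PositionEstimate, view: PlanarSegmentView,
    indices, method: str,
) -> list[OrientationCorrection]:
    if method == "STV":
        return correct_orientation_stv(est, pos, indices)
    if method == "IVN":
        return correct_orientation_ivn(est, pos, view, indices)
    raise ValidationError(f"unknown orientation-correction method {method!r}")


def apply_corrections(
    segment: SpineSegment,
    sagittal_pos: PositionEstimate,
    coronal_pos: PositionEstimate,
    sagittal_corr: list[OrientationCorrection],
    coronal_corr: list[OrientationCorrection],
    *,
    convention: str = "rotvec",
) -> SpineSegment:
    """Reassemble 3-D geometry of the intermediates from the two planes.

    The sagittal estimate supplies the (anterior, inferior) coordinates and
    the coronal estimate the (left, inferior) ones; the duplicated inferior
    coordinate is reconciled by averaging (discrepancies are logged).  The
    combined rotation is the exponential of r = [theta_s, theta_c_axis, 0]
    about the LAI axes applied to the registration-time orientation.  Note
    the anterior-axis component is the *negative* of the in-plane coronal
    angle: with coronal coordinates (left, inferior) a counterclockwise
    in-plane rotation corresponds to a negative rotation about +anterior in
    the right-handed LAI frame.
    """
    idx = [c.index for c in sagittal_corr]
    if idx != [c.index for c in coronal_corr]:
        raise ValidationError("sagittal/coronal corrections cover different vertebrae")
    if len(idx) != sagittal_pos.com2d.shape[0] or len(idx) != coronal_pos.com2d.shape[0]:
        raise ValidationError("position estimates and corrections disagree in length")
    out = segment.copy()
    for j, i in enumerate(idx):
        sag = sagittal_pos.com2d[j]
        cor = coronal_pos.com2d[j]
        dz = abs(sag[1] - cor[1])
        if dz > _HEIGHT_LOG_TOL:
            logger.info(
                "vertebra %s: sagittal/coronal height differ by %.3g mm; averaging",
                out.vertebrae[i].label, dz,
            )
        z = 0.5 * (sag[1] + cor[1])
        com = lift_to_3d([sag[0], z], "sagittal")
        com[0] = cor[0]
        rot = CorrectionRotation(
            theta_s=sagittal_corr[j].theta_deg,
            theta_c=-coronal_corr[j].theta_deg,
            convention=convention,
        )
        R = rotation_from_plane_angles(rot)[:3, :3]
        init = segment.initial[i]
        v = out.vertebrae[i]
        v.com = com
        v.n_sup = R @ init.n_sup
        v.n_inf = R @ init.n_inf
        pose = init.pose.copy()
        pose[:3, :3] = R @ pose[:3, :3]
        pose[:3, 3] = com
        v.pose = pose
        v.stale = False
    return out
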