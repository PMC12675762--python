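"""Vertebra / spine-segment data model and tracked-pose bookkeeping.

A :class:`SpineSegment` holds an ordered (superior to inferior) list of
vertebrae, each with a center of mass (CoM, mm, LAI coordinates), unit
superior/inferior endplate normals, and a rigid pose.  The first and last
vertebrae of an estimation span carry optical-tracker rigid bodies; the
superior tracked vertebra is held fixed as the reference frame throughout
surgery, and every other tracked vertebra's motion is expressed relative to
it, which makes all downstream angles invariant to how the patient (and the
tracker) moves as a whole.
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CoincidentTrackedError,
    GeometryError,
    ValidationError,
)
from .geometry import (
    PlaneTag,
    invert_rigid,
    make_transform,
    project_direction,
    project_to_plane,
    unit,
    validate_rigid,
)

logger = logging.getLogger("spinecurve")

FORMAT_VERSION = 1


@dataclass
class Vertebra:
    """One rigid vertebra: label, CoM (mm), unit endplate normals, pose.

    ``n_sup`` points cranially (away from the body through the superior
    endplate), ``n_inf`` caudally.  Inputs violating this convention
    (``n_sup . n_inf >= 0`` in an implausible way) trigger a warning, not a
    failure, since mild endplate wedging is anatomically real.
    """

    label: str
    com: np.ndarray
    n_sup: np.ndarray
    n_inf: np.ndarray
    pose: np.ndarray = None
    stale: bool = False

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float)
        if self.com.shape != (3,) or not np.all(np.isfinite(self.com)):
            raise ValidationError(f"{self.label}: CoM must be a finite 3-vector")
        self.n_sup = unit(np.asarray(self.n_sup, dtype=float))
        self.n_inf = unit(np.asarray(self.n_inf, dtype=float))
        if float(np.dot(self.n_sup, self.n_inf)) >= 0.0:
            warnings.warn(
                f"{self.label}: endplate normals do not oppose "
                "(n_sup . n_inf >= 0); check the orientation convention",
                stacklevel=2,
            )
        if self.pose is None:
            self.pose = make_transform(t=self.com)
        self.pose = validate_rigid(self.pose)

    def copy(self) -> "Vertebra":
        return Vertebra(
            label=self.label,
            com=self.com.copy(),
            n_sup=self.n_sup.copy(),
            n_inf=self.n_inf.copy(),
            pose=self.pose.copy(),
            stale=self.stale,
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "com": self.com.tolist(),
            "n_sup": self.n_sup.tolist(),
            "n_inf": self.n_inf.tolist(),
            "pose": self.pose.tolist(),
        }


@dataclass
class PlanarSegmentView:
    """2-D projections of a segment into one anatomical plane.

    ``d_pos`` is the in-plane straight-line distance between the projected
    tracked CoMs at estimation time; ``h_t`` the height (v-coordinate)
    difference between them.
    """

    plane: PlaneTag
    com2d: np.ndarray          # (n, 2)
    n_sup2d: np.ndarray        # (n, 2), renormalised
    n_inf2d: np.ndarray        # (n, 2), renormalised
    d_pos: float
    h_t: float


def relative_pose(T_ots_vr0, T_ots_vri) -> np.ndarray:
    """Pose of tracked vertebra i relative to the fixed reference VR_0.

    Returns ``inv(T_ots_vr0) @ T_ots_vri``; composing the reference pose with
    the result reproduces the input pose exactly, and any rigid motion common
    to both poses cancels.
    """
    T0 = validate_rigid(T_ots_vr0)
    Ti = validate_rigid(T_ots_vri)
    return invert_rigid(T0) @ Ti


def chain_fractions(coms, *, mode: str = "chain") -> np.ndarray:
    """Fractional positions of the intermediate vertebrae along the CT chain.

    ``%d_i`` is the cumulative distance from the first CoM to CoM i along the
    polyline of consecutive CoMs, divided by the total chain length, for
    i = 1 .. n-2.  ``mode="straight"`` instead uses the straight-line distance
    from the first CoM (available for comparison; chain is the default since
    it preserves ordering on curved spines).
    """
    coms = np.asarray(coms, dtype=float)
    if coms.ndim != 2 or coms.shape[0] < 3 or coms.shape[1] not in (2, 3):
        raise ValidationError("chain_fractions needs >= 3 CoMs of dim 2 or 3")
    gaps = np.linalg.norm(np.diff(coms, axis=0), axis=1)
    if np.any(gaps < 1e-9):
        raise ValidationError("consecutive CoMs must be distinct")
    if mode == "chain":
        cum = np.cumsum(gaps)
        frac = cum[:-1] / cum[-1]
    elif mode == "straight":
        d = np.linalg.norm(coms - coms[0], axis=1)
        if d[-1] < 1e-9:
            raise ValidationError("first and last CoM coincide")
        frac = d[1:-1] / d[-1]
    else:
        raise ValidationError(f"unknown fraction mode {mode!r}")
    if np.any(np.diff(frac) <= 0) or frac[0] <= 0 or frac[-1] >= 1:
        raise ValidationError("fractions must be strictly increasing in (0, 1)")
    return frac


@dataclass
class SpineSegment:
    """Ordered vertebrae (superior to inferior) with tracked endpoints.

    ``initial`` is the registration-time (CT) snapshot of all vertebrae; it
    is taken automatically at construction and is the reference every update
    composes onto (corrections never accumulate frame-to-frame).
    ``registration_ots`` stores the tracker poses observed at registration
    for each tracked vertebra (identity by default, i.e. tracker poses are
    reported as motion relative to registration).
    """

    vertebrae: list[Vertebra]
    tracked_indices: tuple[int, ...] = None
    initial: list[Vertebra] = field(default=None, repr=False)
    registration_ots: dict[int, np.ndarray] = field(default=None, repr=False)
    fraction_mode: str = "chain"

    def __post_init__(self):
        if len(self.vertebrae) < 2:
            raise ValidationError("a segment needs at least 2 vertebrae")
        n = len(self.vertebrae)
        if self.tracked_indices is None:
            self.tracked_indices = (0, n - 1)
        self.tracked_indices = tuple(sorted(int(i) for i in self.tracked_indices))
        if 0 not in self.tracked_indices or n - 1 not in self.tracked_indices:
            raise ValidationError(
                "the first and last vertebrae must be tracked for estimation"
            )
        labels = [v.label for v in self.vertebrae]
        if len(set(labels)) != n:
            raise ValidationError("vertebra labels must be unique")
        if self.initial is None:
            self.initial = [v.copy() for v in self.vertebrae]
        if self.registration_ots is None:
            self.registration_ots = {i: np.eye(4) for i in self.tracked_indices}
        else:
            self.registration_ots = {
                int(i): validate_rigid(T) for i, T in self.registration_ots.items()
            }

    # -- basic introspection -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.vertebrae)

    @property
    def labels(self) -> list[str]:
        return [v.label for v in self.vertebrae]

    @property
    def intermediate_indices(self) -> list[int]:
        return [i for i in range(self.n) if i not in self.tracked_indices]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown vertebra label {label!r}") from None

    def fractions(self) -> np.ndarray:
        """Chain fractions of the intermediates from the CT-time CoMs."""
        return chain_fractions(
            [v.com for v in self.initial], mode=self.fraction_mode
        )

    def copy(self) -> "SpineSegment":
        return SpineSegment(
            vertebrae=[v.copy() for v in self.vertebrae],
            tracked_indices=self.tracked_indices,
            initial=[v.copy() for v in self.initial],
            registration_ots={i: T.copy() for i, T in self.registration_ots.items()},
            fraction_mode=self.fraction_mode,
        )

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "orientation": "LAI",
            "vertebrae": [v.to_dict() for v in self.vertebrae],
            "tracked": [self.vertebrae[i].label for i in self.tracked_indices],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SpineSegment":
        if d.get("orientation", "LAI") != "LAI":
            raise ValidationError("only LAI orientation is supported")
        try:
            verts = [
                Vertebra(
                    label=v["label"],
                    com=v["com"],
                    n_sup=v["n_sup"],
                    n_inf=v["n_inf"],
                    pose=np.asarray(v["pose"], dtype=float) if "pose" in v else None,
                )
                for v in d["vertebrae"]
            ]
        except KeyError as e:
            raise ValidationError(f"vertebra entry missing field {e}") from None
        labels = [v.label for v in verts]
        tracked = d.get("tracked")
        if tracked is None:
            idx = None
        else:
            missing = [t for t in tracked if t not in labels]
            if missing:
                raise ValidationError(f"tracked labels not in segment: {missing}")
            idx = tuple(labels.index(t) for t in tracked)
        return cls(vertebrae=verts, tracked_indices=idx)

    @classmethod
    def from_json(cls, path) -> "SpineSegment":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def planar_view(segment: SpineSegment, plane: PlaneTag) -> PlanarSegmentView:
    """Project a segment's current geometry into one anatomical plane."""
    com2d = np.array([project_to_plane(v.com, plane) for v in segment.vertebrae])
    n_sup2d = np.array(
        [project_direction(v.n_sup, plane) for v in segment.vertebrae]
    )
    n_inf2d = np.array(
        [project_direction(v.n_inf, plane) for v in segment.vertebrae]
    )
    chord = com2d[-1] - com2d[0]
    d_pos = float(np.linalg.norm(chord))
    if d_pos < 1e-6:
        raise CoincidentTrackedError(
            f"tracked CoMs coincide in the {plane} plane (d_pos={d_pos:g})"
        )
    h_t = float(com2d[-1, 1] - com2d[0, 1])
    return PlanarSegmentView(
        plane=plane, com2d=com2d, n_sup2d=n_sup2d, n_inf2d=n_inf2d,
        d_pos=d_pos, h_t=h_t,
    )


def update_tracked_poses(
    segment: SpineSegment, ots_poses: dict[int, np.ndarray]
) -> SpineSegment:
    """Move the tracked vertebrae according to new optical-tracker poses.

    The superior tracked vertebra VR_0 stays at its registered pose (it *is*
    the reference frame); every other tracked vertebra is moved by its pose
    relative to VR_0, composed against the relative pose observed at
    registration and applied to the registration-time geometry.  Untracked
    vertebrae keep their registration geometry and are flagged stale until
    the estimation pipeline re-places them.

    ``ots_poses`` maps vertebra index (or label) to a 4x4 tracker transform
    and must cover every tracked vertebra.
    """
    poses: dict[int, np.ndarray] = {}
    for key, T in ots_poses.items():
        idx = segment.index_of(key) if isinstance(key, str) else int(key)
        poses[idx] = validate_rigid(T)
    missing = [i for i in segment.tracked_indices if i not in poses]
    if missing:
        raise ValidationError(
            f"missing tracker poses for tracked vertebrae {missing}"
        )
    out = segment.copy()
    T0_now = poses[0]
    for i in segment.tracked_indices:
        reg_rel = relative_pose(
            segment.registration_ots[0], segment.registration_ots[i]
        )
        now_rel = relative_pose(T0_now, poses[i])
        motion = now_rel @ invert_rigid(reg_rel)  # motion in the VR_0-fixed frame
        R = motion[:3, :3]
        init = segment.initial[i]
        v = out.vertebrae[i]
        v.com = R @ init.com + motion[:3, 3]
        v.n_sup = R @ init.n_sup
        v.n_inf = R @ init.n_inf
        v.pose = motion @ init.pose
        v.stale = False
    for i in out.intermediate_indices:
        out.vertebrae[i].stale = True
    return out
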