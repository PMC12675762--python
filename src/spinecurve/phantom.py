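"""Synthetic spine phantoms with known ground truth.

The generator emulates the geometry of an ex vivo validation specimen: an
ordered chain of rigid vertebrae whose first and last members carry tracker
references, with every true CoM, endplate normal, and pairwise endplate
angle known exactly.  Three curvature profiles are available:

* ``straight`` - CoMs along the inferior axis, endplates level;
* ``arc``      - a single circular-arc bend of a given total angle in one
  plane, vertebra orientations rotating in equal increments;
* ``v``        - two straight sub-chains meeting at a wedged apex vertebra,
  the shape a vertebral resection produces in a spine whose segments cannot
  themselves bend.

``simulate_correction`` turns one configuration into another by opening a
wedge at an apex vertebra and rigidly re-posing the inferior sub-chain,
returning the post-event ground truth together with the tracker poses the
tracked pair would report - exactly the input the estimation pipeline sees
during surgery.

The default phantom has 6 vertebrae (4 intermediates between the 2 tracked
ends) at 30 mm CoM spacing, a typical lumbar inter-vertebral distance.  All
randomness (position / normal-angle noise) is driven by one seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .geometry import make_transform
from .metrics import pair_labels, pairwise_angles
from .segment import SpineSegment, Vertebra

_PLANE_AXIS = {"sagittal": 0, "coronal": 1}  # rotation axis index (x=left, y=anterior)
_PLANE_SIGN = {"sagittal": 1.0, "coronal": -1.0}  # in-plane CCW -> axis rotation sign


def _plane_rotation(plane: str, angle_deg: float) -> np.ndarray:
    """3-D rotation realising an in-plane CCW rotation of ``angle_deg``.

    Sagittal coordinates are (anterior, inferior) so an in-plane CCW angle is
    a rotation about +left; coronal coordinates are (left, inferior) where an
    in-plane CCW angle is a rotation about -anterior.
    """
    rotvec = np.zeros(3)
    rotvec[_PLANE_AXIS[plane]] = np.deg2rad(angle_deg) * _PLANE_SIGN[plane]
    return Rotation.from_rotvec(rotvec).as_matrix()


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of one synthetic phantom."""

    n_vertebrae: int = 6
    spacing: float | tuple = 30.0          # mm, scalar or per-gap list (n-1)
    profile: str = "straight"              # straight | arc | v
    arc_angle_deg: float = 0.0             # total bend over the chain (arc)
    bend_plane: str = "sagittal"
    apex: Optional[int] = None             # v profile: apex vertebra index
    wedge_deg: float = 0.0                 # v profile: wedge opening at apex
    endplate_wedge_deg: float = 0.0        # per-vertebra body wedge (all profiles)
    noise_pos_mm: float = 0.0
    noise_normal_deg: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_vertebrae < 3:
            raise ValidationError("phantom needs n_vertebrae >= 3")
        gaps = self.gap_lengths()
        if np.any(gaps <= 0):
            raise ValidationError("spacing must be positive")
        if self.profile not in ("straight", "arc", "v"):
            raise ValidationError(f"unknown profile {self.profile!r}")
        if abs(self.arc_angle_deg) >= 180.0:
            raise ValidationError("|total arc| must be below 180 degrees")
        if self.bend_plane not in _PLANE_AXIS:
            raise ValidationError(f"unknown plane {self.bend_plane!r}")
        if self.profile == "v":
            a = self.apex_index()
            if a <= 0 or a >= self.n_vertebrae - 1:
                raise ValidationError("v-profile apex must be an intermediate vertebra")
        if self.noise_pos_mm < 0 or self.noise_normal_deg < 0:
            raise ValidationError("noise levels must be non-negative")

    def gap_lengths(self) -> np.ndarray:
        s = np.asarray(self.spacing, dtype=float)
        if s.ndim == 0:
            return np.full(self.n_vertebrae - 1, float(s))
        if s.shape != (self.n_vertebrae - 1,):
            raise ValidationError(
                f"per-gap spacing needs {self.n_vertebrae - 1} entries"
            )
        return s

    def apex_index(self) -> int:
        return self.apex if self.apex is not None else self.n_vertebrae // 2


@dataclass(frozen=True)
class GroundTruth:
    """The noiseless true configuration, kept apart from the observable segment."""

    labels: tuple[str, ...]
    coms: np.ndarray       # (n, 3)
    n_sup: np.ndarray      # (n, 3)
    n_inf: np.ndarray      # (n, 3)
    tracked_indices: tuple[int, ...]
    angles: dict = field(default_factory=dict)  # plane -> (n_pairs,) array

    @property
    def pairs(self) -> tuple[str, ...]:
        return pair_labels(self.labels)

    def to_segment(self) -> SpineSegment:
        """Materialise the truth as a segment (for angle recomputation only)."""
        verts = [
            Vertebra(label=l, com=c, n_sup=s, n_inf=i)
            for l, c, s, i in zip(self.labels, self.coms, self.n_sup, self.n_inf)
        ]
        return SpineSegment(vertebrae=verts, tracked_indices=self.tracked_indices)


def _truth_from_arrays(labels, coms, n_sup, n_inf, tracked) -> GroundTruth:
    gt = GroundTruth(
        labels=tuple(labels),
        coms=np.asarray(coms, dtype=float),
        n_sup=np.asarray(n_sup, dtype=float),
        n_inf=np.asarray(n_inf, dtype=float),
        tracked_indices=tuple(tracked),
    )
    seg = gt.to_segment()
    gt.angles.update(
        {p: pairwise_angles(seg, p) for p in ("sagittal", "coronal")}
    )
    return gt


def _vertebra_angles(spec: PhantomSpec) -> np.ndarray:
    """In-plane orientation (deg) of each vertebra's body axis, per profile."""
    n = spec.n_vertebrae
    if spec.profile == "straight":
        return np.zeros(n)
    if spec.profile == "arc":
        step = spec.arc_angle_deg / (n - 1)
        return step * np.arange(n)
    # v: superior chain level, inferior chain rotated by the wedge
    a = spec.apex_index()
    ang = np.zeros(n)
    ang[a + 1:] = spec.wedge_deg
    return ang


def generate_phantom(spec: PhantomSpec) -> tuple[SpineSegment, GroundTruth]:
    """Build the observable segment and its exact ground truth.

    The CoM chain is a polyline whose gap directions are the mean of the
    adjacent vertebra orientations (for an arc this reproduces circular-arc
    chord geometry); each vertebra's endplate normals are aligned with its
    body axis, optionally wedged.  Noise perturbs only the *observable*
    segment - the returned ground truth stays exact.
    """
    spec.validate()
    n = spec.n_vertebrae
    gaps = spec.gap_lengths()
    ang = _vertebra_angles(spec)
    plane = spec.bend_plane

    axis_dir = np.array([0.0, 0.0, 1.0])  # caudal body axis of a level vertebra
    coms = np.zeros((n, 3))
    if spec.profile == "v":
        # sub-chains stay straight: each gap follows its inferior vertebra,
        # so the bend happens entirely at the apex
        gap_ang = ang[1:].copy()
    else:
        gap_ang = 0.5 * (ang[:-1] + ang[1:])
    for k in range(1, n):
        d = _plane_rotation(plane, gap_ang[k - 1]) @ axis_dir
        coms[k] = coms[k - 1] + gaps[k - 1] * d

    n_sup = np.zeros((n, 3))
    n_inf = np.zeros((n, 3))
    half_wedge = 0.5 * spec.endplate_wedge_deg
    for k in range(n):
        body = _plane_rotation(plane, ang[k])
        n_inf[k] = _plane_rotation(plane, half_wedge) @ body @ axis_dir
        n_sup[k] = _plane_rotation(plane, -half_wedge) @ body @ (-axis_dir)
    if spec.profile == "v":
        # the apex vertebra is the wedged one: its inferior endplate follows
        # the inferior sub-chain
        a = spec.apex_index()
        n_inf[a] = _plane_rotation(plane, spec.wedge_deg) @ n_inf[a]

    labels = tuple(f"V{k + 1}" for k in range(n))
    tracked = (0, n - 1)
    truth = _truth_from_arrays(labels, coms, n_sup, n_inf, tracked)

    rng = np.random.default_rng(spec.seed)
    obs_coms = coms.copy()
    obs_sup = n_sup.copy()
    obs_inf = n_inf.copy()
    if spec.noise_pos_mm > 0:
        obs_coms = obs_coms + rng.normal(0.0, spec.noise_pos_mm, size=(n, 3))
    if spec.noise_normal_deg > 0:
        for k in range(n):
            for arr in (obs_sup, obs_inf):
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = np.deg2rad(rng.normal(0.0, spec.noise_normal_deg))
                arr[k] = Rotation.from_rotvec(angle * axis).as_matrix() @ arr[k]

    verts = [
        Vertebra(label=l, com=c, n_sup=s, n_inf=i)
        for l, c, s, i in zip(labels, obs_coms, obs_sup, obs_inf)
    ]
    segment = SpineSegment(vertebrae=verts, tracked_indices=tracked)
    return segment, truth


@dataclass(frozen=True)
class CorrectionEvent:
    """Result of a simulated deformity-correction event."""

    truth: GroundTruth
    ots_poses: dict  # label -> 4x4 tracker pose (motion relative to registration)
    apex: str
    wedge_sagittal_deg: float
    wedge_coronal_deg: float


def simulate_correction(
    truth: GroundTruth,
    apex: str | int,
    wedge_sagittal_deg: float = 0.0,
    wedge_coronal_deg: float = 0.0,
) -> CorrectionEvent:
    """Open a wedge at an apex vertebra and rigidly re-pose the chain below.

    Models the geometric effect of a posterior vertebral resection: the
    sub-chain superior to the apex stays put, the apex vertebra's inferior
    endplate and the entire inferior sub-chain rotate about the apex CoM by
    the requested in-plane wedge angles.  Returns the post-event ground truth
    and the tracker poses of the tracked pair (superior reference: identity).
    """
    labels = list(truth.labels)
    a = labels.index(apex) if isinstance(apex, str) else int(apex)
    if a not in range(len(labels)):
        raise ValidationError(f"apex {apex!r} not in the segment")
    if a in (truth.tracked_indices[0], truth.tracked_indices[-1]):
        raise ValidationError("apex must be an intermediate vertebra, not a tracked end")

    R = (
        _plane_rotation("sagittal", wedge_sagittal_deg)
        @ _plane_rotation("coronal", wedge_coronal_deg)
    )
    pivot = truth.coms[a]
    motion = make_transform(R=R, t=pivot - R @ pivot)

    coms = truth.coms.copy()
    n_sup = truth.n_sup.copy()
    n_inf = truth.n_inf.copy()
    n_inf[a] = R @ n_inf[a]  # the apex wedge opens at its inferior endplate
    for k in range(a + 1, len(labels)):
        coms[k] = R @ coms[k] + motion[:3, 3]
        n_sup[k] = R @ n_sup[k]
        n_inf[k] = R @ n_inf[k]

    new_truth = _truth_from_arrays(labels, coms, n_sup, n_inf, truth.tracked_indices)
    poses = {labels[truth.tracked_indices[0]]: np.eye(4)}
    for i in truth.tracked_indices[1:]:
        poses[labels[i]] = motion if i > a else np.eye(4)
    return CorrectionEvent(
        truth=new_truth,
        ots_poses=poses,
        apex=labels[a],
        wedge_sagittal_deg=float(wedge_sagittal_deg),
        wedge_coronal_deg=float(wedge_coronal_deg),
    )
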