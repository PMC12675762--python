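"""Exception hierarchy for the geometric pipeline.

Every error that can surface during an intraoperative update derives from
:class:`SpineCurveError` so callers can catch one base class; the concrete
subclasses name the geometric degeneracy that occurred.
"""


class SpineCurveError(Exception):
    """Base class for all package errors."""


class GeometryError(SpineCurveError, ValueError):
    """Invalid geometric input (zero vector, t outside [0, 1], ...)."""


class NonRigidTransformError(SpineCurveError, ValueError):
    """A 4x4 matrix failed the rigid-transform invariants."""


class DegenerateProjectionError(GeometryError):
    """A direction vector became (numerically) zero after in-plane projection."""


class CoincidentTrackedError(GeometryError):
    """The two tracked centers of mass project to the same in-plane point."""


class NoIntersectionError(GeometryError):
    """A perpendicular line does not meet the estimated curve on t in [0, 1]."""


class OutOfRangeError(GeometryError):
    """A height target lies outside the v-range spanned by the curve."""


class ValidationError(SpineCurveError, ValueError):
    """Malformed segment description, phantom spec, or pose stream."""
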