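"""Pairwise endplate angles, feedback tables, and accuracy statistics.

The clinical feedback surface is, per anatomical plane, the Cobb-style angle
between the superior endplate of the superior vertebra and the inferior
endplate of the inferior vertebra for every vertebra pair, displayed as
Baseline (registration time), Simulated (current), and delta columns.
Accuracy against a reference assessment is summarised by the RMSE over the
pairs and the min/max absolute error with their pair labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import PlaneTag, project_direction, signed_angle
from .segment import SpineSegment, Vertebra


def endplate_angle(sup: Vertebra, inf: Vertebra, plane: PlaneTag) -> float:
    """Acute in-plane angle (degrees, [0, 90]) between two endplate lines.

    Uses the superior endplate of ``sup`` and the inferior endplate of
    ``inf``.  The angle between the endplate *lines* equals the angle between
    the projected normal lines, folded to the acute range (a magnitude, like
    a Cobb measurement).
    """
    a = project_direction(sup.n_sup, plane)
    b = project_direction(inf.n_inf, plane)
    cosang = abs(float(np.dot(a, b)))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def endplate_angle_signed(sup: Vertebra, inf: Vertebra, plane: PlaneTag) -> float:
    """Signed angle variant (direction-of-correction semantics), (-180, 180]."""
    a = project_direction(sup.n_sup, plane)
    b = project_direction(inf.n_inf, plane)
    return signed_angle(a, b)


@dataclass(frozen=True)
class AlignmentTable:
    """Per-plane Baseline / Simulated / delta table over all vertebra pairs."""

    plane: PlaneTag
    pairs: tuple[str, ...]
    baseline: np.ndarray
    simulated: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        """simulated - baseline (positive: angle increased intraoperatively)."""
        return self.simulated - self.baseline

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": self.pairs,
                "baseline_deg": self.baseline,
                "simulated_deg": self.simulated,
                "delta_deg": self.delta,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    def __str__(self) -> str:  # console rendering of the feedback table
        df = self.to_frame().round(2)
        return f"[{self.plane}]\n{df.to_string(index=False)}"


def pair_labels(labels) -> tuple[str, ...]:
    """All unordered vertebra pairs, superior listed first."""
    return tuple(f"{a}-{b}" for a, b in combinations(labels, 2))


def pairwise_angles(segment: SpineSegment, plane: PlaneTag) -> np.ndarray:
    """Endplate angles for every vertebra pair of the segment, table order."""
    return np.array(
        [
            endplate_angle(segment.vertebrae[i], segment.vertebrae[j], plane)
            for i, j in combinations(range(segment.n), 2)
        ]
    )


def alignment_table(
    segment: SpineSegment, plane: PlaneTag, baseline: SpineSegment
) -> AlignmentTable:
    """Build the feedback table: baseline vs current pairwise angles."""
    if segment.labels != baseline.labels:
        raise ValidationError(
            f"label mismatch: {segment.labels} vs baseline {baseline.labels}"
        )
    return AlignmentTable(
        plane=plane,
        pairs=pair_labels(segment.labels),
        baseline=pairwise_angles(baseline, plane),
        simulated=pairwise_angles(segment, plane),
    )


def rmse(a, b) -> float:
    """Root mean squared error between two equal-length angle lists."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValidationError("rmse needs two equal nonzero-length lists")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass(frozen=True)
class ErrorSummary:
    """RMSE plus absolute-error extrema with their pair labels."""

    rmse: float
    min_abs: float
    min_label: str
    max_abs: float
    max_label: str


def abs_error_extrema(a, b, labels) -> ErrorSummary:
    """Min/max absolute error between two angle lists, labelled."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    labels = list(labels)
    if a.shape != b.shape or len(labels) != a.size or a.size == 0:
        raise ValidationError("abs_error_extrema needs equal-length inputs")
    err = np.abs(a - b)
    i_min, i_max = int(np.argmin(err)), int(np.argmax(err))
    return ErrorSummary(
        rmse=rmse(a, b),
        min_abs=float(err[i_min]),
        min_label=labels[i_min],
        max_abs=float(err[i_max]),
        max_label=labels[i_max],
    )
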