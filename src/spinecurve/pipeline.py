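"""End-to-end intraoperative estimation pipeline and the method matrix.

One update cycle runs, per anatomical plane: tracked-pose update -> planar
projection -> curve estimation (EN or ENIP) -> position estimation (H or P)
-> orientation correction (STV or IVN) -> 3-D reassembly -> pairwise-angle
feedback tables.  The 2 x 2 x 2 combinations form the eight evaluation
methods M1-M8; the labels are display sugar, all logic keys on the explicit
triple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .curve_estimation import CurveEstimate, estimate_curve
from .errors import ValidationError
from .metrics import (
    AlignmentTable,
    ErrorSummary,
    abs_error_extrema,
    alignment_table,
    pair_labels,
    pairwise_angles,
)
from .orientation import (
    OrientationCorrection,
    apply_corrections,
    correct_orientation,
)
from .position_estimation import PositionEstimate, estimate_positions
from .segment import SpineSegment, planar_view, update_tracked_poses

logger = logging.getLogger("spinecurve")

PLANES = ("sagittal", "coronal")


@dataclass(frozen=True)
class MethodConfig:
    """One (curve, position, orientation) combination."""

    curve: str          # EN | ENIP
    position: str       # H | P
    orientation: str    # STV | IVN
    label: Optional[str] = None

    def __post_init__(self):
        if self.curve not in ("EN", "ENIP"):
            raise ValidationError(f"curve method must be EN or ENIP, got {self.curve!r}")
        if self.position not in ("H", "P"):
            raise ValidationError(f"position method must be H or P, got {self.position!r}")
        if self.orientation not in ("STV", "IVN"):
            raise ValidationError(
                f"orientation method must be STV or IVN, got {self.orientation!r}"
            )
        if self.label is not None and self.label in _METHOD_MATRIX:
            expect = _METHOD_MATRIX[self.label]
            if (self.curve, self.position, self.orientation) != expect:
                raise ValidationError(
                    f"label {self.label} maps to {expect}, not "
                    f"({self.curve}, {self.position}, {self.orientation})"
                )

    def __str__(self) -> str:
        tag = f"{self.label}: " if self.label else ""
        return f"{tag}CE_{self.curve} + PE_{self.position} + OC_{self.orientation}"


#: Reconstructed M-label mapping: M5-M8 use IVN, M8 = (ENIP, H, IVN),
#: M6 = (ENIP, P, IVN); within each block EN/ENIP alternate.
_METHOD_MATRIX: dict[str, tuple[str, str, str]] = {
    "M1": ("EN", "H", "STV"),
    "M2": ("ENIP", "H", "STV"),
    "M3": ("EN", "P", "STV"),
    "M4": ("ENIP", "P", "STV"),
    "M5": ("EN", "P", "IVN"),
    "M6": ("ENIP", "P", "IVN"),
    "M7": ("EN", "H", "IVN"),
    "M8": ("ENIP", "H", "IVN"),
}


def enumerate_methods() -> list[MethodConfig]:
    """The eight evaluation methods, M1 through M8."""
    return [
        MethodConfig(curve=c, position=p, orientation=o, label=m)
        for m, (c, p, o) in _METHOD_MATRIX.items()
    ]


def method_by_label(label: str) -> MethodConfig:
    if label not in _METHOD_MATRIX:
        raise ValidationError(f"unknown method label {label!r} (use M1..M8)")
    c, p, o = _METHOD_MATRIX[label]
    return MethodConfig(curve=c, position=p, orientation=o, label=label)


@dataclass
class PipelineReport:
    """Full provenance of one estimation cycle."""

    config: MethodConfig
    segment: SpineSegment                       # corrected geometry
    curves: dict[str, CurveEstimate]
    positions: dict[str, PositionEstimate]
    corrections: dict[str, list[OrientationCorrection]]
    tables: dict[str, AlignmentTable]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "method": {
                "curve": self.config.curve,
                "position": self.config.position,
                "orientation": self.config.orientation,
                "label": self.config.label,
            },
            "curves": {p: c.to_dict() for p, c in self.curves.items()},
            "positions": {
                p: {
                    "com2d": e.com2d.tolist(),
                    "t": e.t.tolist(),
                    "fallback": e.fallback.tolist(),
                }
                for p, e in self.positions.items()
            },
            "corrections": {
                p: [
                    {"index": c.index, "theta_deg": c.theta_deg, "method": c.method}
                    for c in corr
                ]
                for p, corr in self.corrections.items()
            },
            "tables": {
                p: t.to_frame().to_dict(orient="list") for p, t in self.tables.items()
            },
            "warnings": self.warnings,
            "segment": self.segment.to_dict(),
        }


def run_pipeline(
    segment: SpineSegment,
    ots_poses: dict,
    config: MethodConfig,
    *,
    strict: bool = False,
    rotation_convention: str = "rotvec",
    intervened: Optional[list[str]] = None,
) -> PipelineReport:
    """Execute one full estimation cycle and produce the feedback tables.

    ``intervened`` optionally names vertebrae whose shape was surgically
    altered (e.g. by an osteotomy); the pipeline cannot model the altered
    geometry and computes unchanged, but surfaces a warning for audit.
    """
    warnings_log: list[str] = []
    for lab in intervened or []:
        segment.index_of(lab)  # validate
        warnings_log.append(
            f"vertebra {lab} flagged as intervened: shape changes from the "
            "procedure are not modelled; estimates use registration geometry"
        )
        logger.warning(warnings_log[-1])

    updated = update_tracked_poses(segment, ots_poses)
    baseline = SpineSegment(
        vertebrae=[v.copy() for v in segment.initial],
        tracked_indices=segment.tracked_indices,
    )

    intermediates = updated.intermediate_indices
    if not intermediates:
        tables = {p: alignment_table(updated, p, baseline) for p in PLANES}
        return PipelineReport(
            config=config, segment=updated, curves={}, positions={},
            corrections={}, tables=tables, warnings=warnings_log,
        )

    fractions = updated.fractions()
    curves: dict[str, CurveEstimate] = {}
    positions: dict[str, PositionEstimate] = {}
    corrections: dict[str, list[OrientationCorrection]] = {}
    for plane in PLANES:
        try:
            view = planar_view(updated, plane)
            est = estimate_curve(view, config.curve, fractions)
            pos = estimate_positions(est, view, fractions, config.position, strict=strict)
            corr = correct_orientation(est, pos, view, intermediates, config.orientation)
        except Exception as e:
            e.args = (f"[{plane} / {config}] {e}",) + e.args[1:]
            raise
        curves[plane] = est
        positions[plane] = pos
        corrections[plane] = corr
        for j, fb in enumerate(pos.fallback):
            if fb:
                warnings_log.append(
                    f"{plane}: vertebra {updated.labels[intermediates[j]]} "
                    "placed by nearest-point fallback"
                )

    corrected = apply_corrections(
        updated,
        positions["sagittal"],
        positions["coronal"],
        corrections["sagittal"],
        corrections["coronal"],
        convention=rotation_convention,
    )
    tables = {p: alignment_table(corrected, p, baseline) for p in PLANES}
    return PipelineReport(
        config=config, segment=corrected, curves=curves, positions=positions,
        corrections=corrections, tables=tables, warnings=warnings_log,
    )


def evaluate_methods(
    segment: SpineSegment,
    ots_poses: dict,
    truth_angles: dict[str, np.ndarray],
    *,
    configs: Optional[list[MethodConfig]] = None,
) -> pd.DataFrame:
    """Run every method and score its pairwise angles against ground truth.

    ``truth_angles`` maps plane -> the true angles over all vertebra pairs in
    table order.  Returns a tidy frame with one row per (method, plane):
    columns method, curve, position, orientation, plane, rmse_deg,
    min_abs_deg, min_pair, max_abs_deg, max_pair.
    """
    configs = configs if configs is not None else enumerate_methods()
    labels = pair_labels(segment.labels)
    for plane, truth in truth_angles.items():
        if np.asarray(truth).shape != (len(labels),):
            raise ValidationError(
                f"{plane}: truth must cover the {len(labels)} vertebra pairs"
            )
    rows = []
    for cfg in configs:
        report = run_pipeline(segment, ots_poses, cfg)
        for plane, truth in truth_angles.items():
            got = pairwise_angles(report.segment, plane)
            summ: ErrorSummary = abs_error_extrema(got, np.asarray(truth), labels)
            rows.append(
                {
                    "method": cfg.label or str(cfg),
                    "curve": cfg.curve,
                    "position": cfg.position,
                    "orientation": cfg.orientation,
                    "plane": plane,
                    "rmse_deg": summ.rmse,
                    "min_abs_deg": summ.min_abs,
                    "min_pair": summ.min_label,
                    "max_abs_deg": summ.max_abs,
                    "max_pair": summ.max_label,
                }
            )
    return pd.DataFrame(rows)
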