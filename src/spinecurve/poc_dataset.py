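"""Reference measurements from the ex vivo porcine proof-of-concept study.

A lumbar porcine segment (evaluable vertebrae L1-L4, references screwed to
L1 and L4) was taken from a neutral configuration to a "V"-shaped lordotic
one by a Ponte osteotomy at L3.  At four stages, the six pairwise endplate
angles (coronal and sagittal) were assessed by:

* ``manual``   - blinded manual measurement on the CT scan (the gold
  standard the RMSE column refers to),
* ``system``   - the navigation system measuring directly from the
  segmented CT (no intraoperative estimation involved; the postoperative
  system row is based on an erroneous segmentation and is kept only for
  completeness), and
* ``M1``..``M8`` - the eight intraoperative estimation methods (curve x
  position x orientation combinations), which see only the two tracked
  vertebrae.

Angles are degrees, printed at two decimals; each row's ``rmse`` is the
published root-mean-square error of that row against the same stage's
manual row (divisor 6).  The dataset is the fixture for the statistics
reproduction tests and for the ``evaluate --poc-fixture`` command.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PAIRS: tuple[str, ...] = ("L1-L2", "L1-L3", "L1-L4", "L2-L3", "L2-L4", "L3-L4")

STAGES: tuple[str, ...] = ("preoperative", "postoperative")
SOURCES: tuple[str, ...] = (
    "manual", "system", "M1", "M2", "M3", "M4", "M5", "M6", "M7", "M8",
)
PLANES: tuple[str, ...] = ("coronal", "sagittal")


@dataclass(frozen=True)
class PocRow:
    """One measurement row: six pairwise angles per plane plus printed RMSE."""

    stage: str
    source: str
    coronal: tuple[float, ...]
    rmse_coronal: float
    sagittal: tuple[float, ...]
    rmse_sagittal: float

    def angles(self, plane: str) -> np.ndarray:
        return np.array(getattr(self, plane))

    def printed_rmse(self, plane: str) -> float:
        return getattr(self, f"rmse_{plane}")


_ROWS: dict[tuple[str, str], PocRow] = {}


def _row(stage, source, coronal, rc, sagittal, rs):
    _ROWS[(stage, source)] = PocRow(
        stage, source, tuple(coronal), rc, tuple(sagittal), rs
    )


# fmt: off
_row("preoperative", "manual", (1.44, 2.90, 1.19, 3.80, 2.09, 3.93), 0.00,
     (1.98, 4.59, 1.21, 6.29, 1.25, 1.08), 0.00)
_row("preoperative", "system", (1.75, 2.34, 0.45, 2.68, 0.11, 5.71), 1.25,
     (1.86, 5.37, 0.90, 5.34, 0.93, 1.87), 0.63)
_row("preoperative", "M1", (2.18, 3.44, 0.47, 3.35, 0.38, 5.86), 1.17,
     (9.46, 12.65, 0.95, 5.03, 8.57, 9.18), 6.35)
_row("preoperative", "M2", (1.97, 2.99, 0.51, 3.11, 0.32, 5.68), 1.11,
     (10.75, 14.07, 0.94, 5.15, 9.45, 10.19), 7.28)
_row("preoperative", "M3", (2.21, 3.79, 0.45, 3.68, 0.34, 6.22), 1.31,
     (13.56, 12.66, 1.07, 4.95, 12.80, 9.31), 8.19)
_row("preoperative", "M4", (1.99, 3.04, 0.48, 3.05, 0.31, 5.56), 1.10,
     (10.86, 14.22, 0.96, 5.24, 10.24, 9.40), 7.33)
_row("preoperative", "M5", (1.58, 2.80, 0.50, 2.69, 1.44, 4.79), 0.71,
     (4.24, 7.89, 0.97, 5.54, 4.61, 3.02), 2.30)
_row("preoperative", "M6", (1.73, 2.47, 0.49, 2.53, 1.52, 5.03), 0.81,
     (3.97, 7.42, 1.04, 4.81, 3.52, 3.47), 2.04)
_row("preoperative", "M7", (1.60, 2.72, 0.47, 2.74, 1.43, 4.82), 0.70,
     (4.86, 8.34, 1.01, 5.73, 4.24, 3.65), 2.53)
_row("preoperative", "M8", (1.76, 2.44, 0.46, 2.65, 1.55, 4.89), 0.75,
     (3.59, 7.25, 1.03, 4.64, 3.44, 3.39), 1.94)

_row("postoperative", "manual", (0.83, 3.43, 0.17, 2.60, 1.01, 0.17), 0.00,
     (4.00, 17.25, 19.66, 17.60, 20.00, 2.41), 0.00)
_row("postoperative", "system", (24.55, 22.92, 21.25, 10.71, 9.04, 45.35), 24.35,
     (25.80, 15.61, 27.37, 2.19, 13.94, 12.20), 12.30)
_row("postoperative", "M1", (0.24, 0.79, 0.03, 3.21, 2.40, 4.02), 2.02,
     (9.27, 12.40, 19.93, 1.29, 8.81, 3.13), 8.59)
_row("postoperative", "M2", (0.69, 0.98, 0.06, 3.85, 2.81, 4.27), 2.15,
     (8.98, 13.34, 19.88, 2.51, 9.05, 2.14), 8.04)
_row("postoperative", "M3", (0.23, 0.79, 0.05, 3.21, 2.38, 4.04), 2.02,
     (9.57, 12.54, 19.90, 1.12, 8.48, 2.97), 8.74)
_row("postoperative", "M4", (0.68, 0.98, 0.05, 3.84, 2.81, 4.26), 2.14,
     (8.58, 13.20, 19.89, 2.77, 9.46, 2.29), 7.84)
_row("postoperative", "M5", (1.19, 3.38, 0.05, 0.04, 3.29, 0.21), 1.41,
     (5.76, 11.13, 19.89, 3.51, 12.27, 4.41), 7.10)
_row("postoperative", "M6", (1.62, 3.19, 0.06, 0.58, 3.71, 0.01), 1.42,
     (5.52, 12.14, 19.91, 4.76, 12.53, 3.43), 6.46)
_row("postoperative", "M7", (1.17, 3.36, 0.04, 0.04, 3.29, 0.20), 1.41,
     (6.04, 11.27, 19.90, 3.37, 12.00, 4.28), 7.19)
_row("postoperative", "M8", (1.63, 3.19, 0.04, 0.58, 3.73, 0.01), 1.43,
     (5.07, 11.94, 19.91, 5.01, 12.98, 3.61), 6.31)
# fmt: on


def poc_row(stage: str, source: str) -> PocRow:
    """Fetch one measurement row of the porcine dataset."""
    try:
        return _ROWS[(stage, source)]
    except KeyError:
        raise KeyError(
            f"no row for stage={stage!r}, source={source!r}; "
            f"stages {STAGES}, sources {SOURCES}"
        ) from None


def all_rows() -> list[PocRow]:
    return [_ROWS[(st, so)] for st in STAGES for so in SOURCES]
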