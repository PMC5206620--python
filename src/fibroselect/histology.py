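"""Semiquantitative histology scoring of renal fibrosis.

Two lesions are scored from percent fibrotic area measured on biopsy
sections: glomerulosclerosis (GS; per-glomerulus grade 0-4, specimen score
= mean grade over all graded glomeruli) and tubulointerstitial fibrosis
(TIF; a single grade 0-3 from the percent fibrotic interstitial area).
Grade 0 denotes absence of TIF; grades 1-3 define the TIF group. Healthy
participants carry no biopsy and are always assigned to the no-TIF group.

Bin boundaries: the published integer anchors (e.g. "1-25%", "26-50%")
leave non-integer percentages such as 25.5 unassigned; the graders here use
half-open bins with upper bounds at the printed anchors so every value in
[0, 100] maps to exactly one grade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "glomerulus_grade",
    "gs_score",
    "tif_grade",
    "tif_label",
    "TifAssessment",
    "assess_tif",
    "MIN_GLOMERULI",
]

#: Minimum glomerulus count for a conforming GS specimen (warn below).
MIN_GLOMERULI = 20


def _check_pct(pct: float, what: str) -> float:
    pct = float(pct)
    if not np.isfinite(pct) or pct < 0.0 or pct > 100.0:
        raise ValueError(f"{what} must be a percentage in [0, 100], got {pct!r}")
    return pct


def glomerulus_grade(pct: float) -> int:
    """Grade a single glomerulus from its percent sclerotic area.

    0 for 0%; 1 for (0, 25]; 2 for (25, 50]; 3 for (50, 75]; 4 for (75, 100].
    """
    pct = _check_pct(pct, "glomerular fibrotic area")
    if pct == 0.0:
        return 0
    if pct <= 25.0:
        return 1
    if pct <= 50.0:
        return 2
    if pct <= 75.0:
        return 3
    return 4


def gs_score(pct_fibrotic: Sequence[float]) -> float:
    """Specimen glomerulosclerosis score: mean per-glomerulus grade, in [0, 4].

    Each graded glomerulus carries weight one. Specimens with fewer than
    ``MIN_GLOMERULI`` glomeruli are scored but trigger a warning, mirroring
    the convention that a conforming specimen contains at least 20.
    """
    pcts = list(pct_fibrotic)
    if len(pcts) == 0:
        raise ValueError("cannot score a specimen with no glomeruli")
    if len(pcts) < MIN_GLOMERULI:
        warnings.warn(
            f"specimen has {len(pcts)} glomeruli (< {MIN_GLOMERULI}); "
            "score may be unreliable",
            stacklevel=2,
        )
    grades = [glomerulus_grade(p) for p in pcts]
    return float(np.mean(grades))


def tif_grade(tif_pct: float) -> int:
    """Grade tubulointerstitial fibrosis from percent fibrotic area.

    0 for [0, 5]; 1 for (5, 25]; 2 for (25, 50]; 3 for (50, 100].
    """
    pct = _check_pct(tif_pct, "tubulointerstitial fibrotic area")
    if pct <= 5.0:
        return 0
    if pct <= 25.0:
        return 1
    if pct <= 50.0:
        return 2
    return 3


def tif_label(grade: int, group: str = "CKD") -> int:
    """Binary TIF status: 1 iff grade >= 1; healthy participants always 0."""
    grade = int(grade)
    if grade not in (0, 1, 2, 3):
        raise ValueError(f"TIF grade must be in 0..3, got {grade}")
    if group == "healthy":
        return 0
    return int(grade >= 1)


@dataclass(frozen=True)
class TifAssessment:
    """A TIF measurement with its derived grade and binary label."""

    tif_pct: float
    tif_grade: int
    tif_label: int


def assess_tif(tif_pct: float, group: str = "CKD") -> TifAssessment:
    """Grade and label a specimen from its interstitial fibrotic-area percent."""
    grade = tif_grade(tif_pct)
    return TifAssessment(float(tif_pct), grade, tif_label(grade, group))
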