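"""Deterministic calculators for common histology and in-vivo assay rubrics.

These are the small scoring conventions used alongside the APA screen when
profiling NUDT21 in tumor cohorts: the immunohistochemistry (IHC) composite
score, the caliper tumor-volume formula, and wound-healing closure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

VALID_INTENSITY = (0, 1, 2, 3)
VALID_PROPORTION = (0, 1, 2, 3, 4)
LOW_HIGH_CUTOFF = 3  # final score <= 3 is "low", 4-12 is "high"


@dataclass(frozen=True)
class IHCScore:
    intensity: int
    proportion: int

    @property
    def final(self) -> int:
        return self.intensity * self.proportion

    @property
    def level(self) -> str:
        return "low" if self.final <= LOW_HIGH_CUTOFF else "high"


def ihc_score(intensity: int, proportion: int) -> IHCScore:
    """Composite IHC score: staining intensity (0-3) x positive-cell
    proportion score (0-4); 0-3 low, 4-12 high."""
    if intensity not in VALID_INTENSITY:
        raise ValueError(f"intensity {intensity!r} not in {VALID_INTENSITY}")
    if proportion not in VALID_PROPORTION:
        raise ValueError(f"proportion {proportion!r} not in {VALID_PROPORTION}")
    return IHCScore(intensity, proportion)


def proportion_bin(percent_positive: float) -> int:
    """Bin percent positive cells: 0 none; 1 <=10%; 2 11-50%; 3 51-80%;
    4 >=80%.

    The published bins overlap at exactly 80%; the "80% or more" bin wins
    there, as the more specific clause.
    """
    p = float(percent_positive)
    if not 0 <= p <= 100:
        raise ValueError(f"percent_positive {p} outside [0, 100]")
    if p == 0:
        return 0
    if p <= 10:
        return 1
    if p <= 50:
        return 2
    if p < 80:
        return 3
    return 4


def tumor_volume(length: float, width: float) -> float:
    """Caliper volume (L x W^2) / 2; mm^3 when inputs are mm."""
    if length < 0 or width < 0:
        raise ValueError("dimensions must be non-negative")
    if width > length:
        warnings.warn(
            f"width {width} exceeds length {length}; computing anyway "
            "(convention is L >= W)"
        )
    return length * width**2 / 2.0


def wound_closure(area_t0: float, area_t: float) -> float:
    """Percent wound-gap closure: 100 * (1 - area_t / area_t0)."""
    if area_t0 <= 0:
        raise ValueError("initial wound area must be positive")
    if area_t < 0:
        raise ValueError("wound area cannot be negative")
    if area_t > area_t0:
        warnings.warn("wound area grew beyond baseline; clipping closure at 0%")
        area_t = area_t0
    return 100.0 * (1.0 - area_t / area_t0)
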