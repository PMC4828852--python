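"""Derived echocardiographic quantities.

Pure functions computing the post-systolic index (PSI), maximal strain,
the wall motion score index (WMSI) and its stress-rest difference ΔWMSI —
the visual covariate that enters every endpoint model.

Missing measurements are represented as ``None`` or ``nan``; the functions
propagate missingness rather than silently treating it as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

__all__ = ["SegmentScore", "psi", "maximal_strain", "wmsi", "delta_wmsi"]

#: Visual wall-motion grades: 1 normal, 2 hypokinetic, 3 akinetic, 4 dyskinetic.
VALID_SCORES = (1, 2, 3, 4)


@dataclass(frozen=True)
class SegmentScore:
    """Semiquantitative visual grade of one segment.

    ``score`` is 1-4 when the segment is interpretable, ``None`` otherwise.
    """

    segment: str
    score: int | None

    def __post_init__(self) -> None:
        if self.score is not None and self.score not in VALID_SCORES:
            raise ValueError(f"segment score must be in {VALID_SCORES}, got {self.score}")

    @property
    def interpretable(self) -> bool:
        return self.score is not None


def _is_missing(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def psi(systolic_strain: float | None, post_systolic_strain: float | None) -> float | None:
    """Post-systolic index: peak post-systolic strain minus peak systolic strain.

    Both strains are percentages (longitudinal strain negative).  A missing
    input propagates to a missing result.
    """
    if _is_missing(systolic_strain) or _is_missing(post_systolic_strain):
        return None
    return post_systolic_strain - systolic_strain


def maximal_strain(
    systolic_strain: float | None, post_systolic_strain: float | None
) -> float | None:
    """Whichever of systolic / post-systolic strain is larger in magnitude.

    Longitudinal strain is negative, so "larger" is read as larger absolute
    deformation; ties return the systolic value.  With one input missing the
    other is returned; with both missing the result is missing.
    """
    sys_missing = _is_missing(systolic_strain)
    post_missing = _is_missing(post_systolic_strain)
    if sys_missing and post_missing:
        return None
    if sys_missing:
        return post_systolic_strain
    if post_missing:
        return systolic_strain
    if abs(post_systolic_strain) > abs(systolic_strain):
        return post_systolic_strain
    return systolic_strain


def wmsi(scores: Iterable[SegmentScore | int | None]) -> float:
    """Wall motion score index: mean visual grade over interpretable segments.

    Accepts :class:`SegmentScore` objects or bare grades (``None`` =
    uninterpretable).  Raises ``ValueError`` when no segment is interpretable.
    """
    values = []
    for s in scores:
        grade = s.score if isinstance(s, SegmentScore) else s
        if grade is None:
            continue
        if grade not in VALID_SCORES:
            raise ValueError(f"segment score must be in {VALID_SCORES}, got {grade}")
        values.append(grade)
    if not values:
        raise ValueError("WMSI undefined: no interpretable segments")
    return sum(values) / len(values)


def delta_wmsi(wmsi_rest: float, wmsi_stress: float) -> float:
    """ΔWMSI = WMSI(stress) − WMSI(rest), the visual model covariate.

    Negative values are allowed (biphasic responses); both inputs must lie
    in the WMSI range [1, 4].
    """
    for name, v in (("wmsi_rest", wmsi_rest), ("wmsi_stress", wmsi_stress)):
        if not (1.0 <= v <= 4.0):
            raise ValueError(f"{name} must lie in [1, 4], got {v}")
    return wmsi_stress - wmsi_rest
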