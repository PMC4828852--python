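"""Diagnostic-accuracy statistics and observer reproducibility.

Sensitivity, specificity and predictive values are reported as percentages
with 95 % confidence intervals (Wilson score by default; Clopper-Pearson
optionally).  Two estimates are called significantly different when their
95 % CIs do not overlap — a deliberately conservative rule.  Observer
agreement is summarized as the mean percentage difference of paired
measurements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "DiagnosticPerformance",
    "ReproducibilityResult",
    "performance",
    "compare_by_ci_overlap",
    "mean_percentage_difference",
    "printed_percentage",
]


def printed_percentage(numerator: int, denominator: int) -> float:
    """100·num/den rounded half-away-from-zero to one decimal.

    Matches the convention of printed clinical tables (e.g. 76 of 151 →
    50.3), where banker's rounding is never used.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    value = 100.0 * numerator / denominator
    return math.copysign(math.floor(abs(value) * 10 + 0.5) / 10, value)


def _ci_percent(count: int, nobs: int, method: str) -> tuple[float, float]:
    if nobs == 0:
        return (math.nan, math.nan)
    alias = {"wilson": "wilson", "clopper-pearson": "beta"}
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method=alias[method])
    return (100.0 * lo, 100.0 * hi)


@dataclass(frozen=True)
class Metric:
    """A proportion as a percentage with its 95 % CI."""

    value: float  # percent; nan when the denominator is empty
    lower: float
    upper: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.lower, self.upper)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Confusion counts with sensitivity/specificity/PPV/NPV.

    An empty denominator (e.g. PPV with no positive predictions) yields an
    explicitly undefined (NaN) metric rather than a silent 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    ci_method: str = "wilson"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.ci_method not in ("wilson", "clopper-pearson"):
            raise ValueError(f"unknown CI method: {self.ci_method!r}")

    def _metric(self, count: int, nobs: int) -> Metric:
        if nobs == 0:
            return Metric(math.nan, math.nan, math.nan)
        lo, hi = _ci_percent(count, nobs, self.ci_method)
        return Metric(100.0 * count / nobs, lo, hi)

    @property
    def sensitivity(self) -> Metric:
        return self._metric(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Metric:
        return self._metric(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Metric:
        return self._metric(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Metric:
        return self._metric(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> Metric:
        return self._metric(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    @property
    def youden_j(self) -> float:
        """Youden's J = sens + spec − 1, on the [−1, 1] scale."""
        return (self.sensitivity.value + self.specificity.value) / 100.0 - 1.0

    def as_row(self) -> dict:
        row: dict = {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            m: Metric = getattr(self, name)
            row[name] = m.value
            row[f"{name}_lo"] = m.lower
            row[f"{name}_hi"] = m.upper
        return row


def performance(
    predictions: Sequence[bool] | np.ndarray,
    labels: Sequence[bool] | np.ndarray,
    ci_method: str = "wilson",
) -> DiagnosticPerformance:
    """Confusion counts and accuracy metrics of binary predictions."""
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    if pred.shape != lab.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("predictions and labels must be equal-length nonempty vectors")
    if lab.all() or not lab.any():
        raise ValueError("labels must contain both classes")
    return DiagnosticPerformance(
        tp=int(np.sum(pred & lab)),
        fp=int(np.sum(pred & ~lab)),
        tn=int(np.sum(~pred & ~lab)),
        fn=int(np.sum(~pred & lab)),
        ci_method=ci_method,
    )


def compare_by_ci_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """True (significant at 0.05) iff the two 95 % CIs do not overlap.

    A shared endpoint counts as overlap (not significant).
    """
    (a_lo, a_hi), (b_lo, b_hi) = a, b
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError("interval bounds must be ordered")
    return max(a_lo, b_lo) > min(a_hi, b_hi)


@dataclass(frozen=True)
class ReproducibilityResult:
    """Mean percentage difference of paired observer measurements."""

    parameter_family: str  # WMSI | velocities | strain | strain rate
    phase: str
    mode: str  # inter | intra
    mean_percentage_difference: float
    n_pairs: int


def mean_percentage_difference(pairs: Sequence[tuple[float, float]]) -> float:
    """Mean over pairs of |v₁ − v₂| / ((v₁ + v₂)/2).

    Pairs averaging to zero are excluded with a warning (the relative
    difference is undefined there).
    """
    if len(pairs) == 0:
        raise ValueError("at least one measurement pair is required")
    diffs = []
    for v1, v2 in pairs:
        mean = (v1 + v2) / 2.0
        if mean == 0:
            warnings.warn("excluding pair with zero mean from mean percentage difference")
            continue
        diffs.append(abs(v1 - v2) / abs(mean))
    if not diffs:
        raise ValueError("no valid pairs (all averaged to zero)")
    return float(np.mean(diffs))
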