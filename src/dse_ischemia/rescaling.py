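"""Step 2 — threshold-anchored rescaling with zero imputation.

Every retained covariate is replaced by a rescaled logistic-regression
response.  With p = φ(β₀ + β₁x) the fitted probability and T the
covariate's optimal classification threshold,

    r(x) = (p − T) / (1 − T)   if p > T
    r(x) = (T − p) / T         if p ≤ T

and a missing value maps to 0.  r measures the normalized distance of the
fitted probability from the classification threshold: it is 0 exactly at
the threshold (and for missing data), approaches 1 deep inside either
class, and is continuous at the branch boundary.  Both branches are
nonnegative, so supra- and sub-threshold deviations are deliberately
indistinguishable downstream — the stepwise model sees "how decisive",
not "which side".  After this step the feature matrix is complete: zero
imputation means a missing measurement simply casts no vote.

The printed form of the branch condition compares the linear predictor
β₀+β₁x with T; since T lives on the probability scale this module applies
the condition to φ(β₀+β₁x), the only reading under which both branch
denominators and the [0,1] range are coherent.  The literal
linear-predictor comparison is available via ``strict_linear_branch``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .screening import ScreenedFeature
from .synthetic import Cohort

__all__ = ["logistic_phi", "rescale", "build_matrix", "RescaledMatrix"]


def logistic_phi(y):
    """Standard logistic function φ(y) = e^y / (1 + e^y), overflow-safe."""
    return expit(y)


def rescale(
    x,
    feature: ScreenedFeature,
    strict_linear_branch: bool = False,
):
    """Rescaled response r(x) for one covariate; missing (NaN) maps to 0.

    Accepts a scalar or array; returns the same shape with every entry in
    [0, 1].
    """
    T = feature.threshold
    if not (0.0 < T < 1.0):
        raise ValueError(f"threshold must lie strictly in (0,1), got {T}")
    x_arr = np.asarray(x, dtype=float)
    lin = feature.beta0 + feature.beta1 * x_arr
    p = expit(lin)
    above = (lin > T) if strict_linear_branch else (p > T)
    r = np.where(above, (p - T) / (1.0 - T), (T - p) / T)
    r = np.where(np.isnan(x_arr), 0.0, r)
    if np.ndim(x) == 0:
        return float(r)
    return r


@dataclass(frozen=True)
class RescaledMatrix:
    """Complete patient × feature matrix of rescaled responses."""

    frame: pd.DataFrame  # index: patient_id; columns: feature keys
    features: tuple[ScreenedFeature, ...]

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("rescaled matrix must not contain missing entries")
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValueError("rescaled entries must lie in [0, 1]")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="patient_id")


def build_matrix(
    cohort: Cohort,
    screened: Sequence[ScreenedFeature],
    strict_linear_branch: bool = False,
) -> RescaledMatrix:
    """Apply :func:`rescale` to every patient × screened-feature cell.

    The output is complete by construction (missing raw values become 0).
    """
    if not screened:
        raise ValueError("screened feature set is empty")
    cols = {}
    for f in screened:
        raw = cohort.covariate(f.parameter, f.segment, f.phase)
        cols[f.key] = rescale(raw, f, strict_linear_branch=strict_linear_branch)
    frame = pd.DataFrame(cols, index=cohort.patients.index)
    return RescaledMatrix(frame=frame, features=tuple(screened))
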