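"""Step 1 — univariable logistic screening with optimal cutoffs.

For each candidate covariate (one quantitative parameter in one segment at
one phase, plus the patient-level ΔWMSI), a simple logistic regression is
fitted against the binary endpoint on complete cases.  Covariates with a
Wald p-value below the significance level are retained, and for each
retained covariate an optimal classification threshold T on the fitted
probability scale is computed (Youden's J by default).  The raw-scale
cutoff — the covariate value at which the fitted probability crosses T —
is stored alongside, which is how such models are conventionally tabulated
(variable, segment, cutoff, unit).

No multiplicity correction is applied across the many univariable tests;
that is a property of the modelled procedure, not an oversight.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit

from .parameters import PARAMETER_NAMES, PHASES
from .segments import SEGMENTS
from .synthetic import Cohort

__all__ = [
    "UnivariableFit",
    "ScreenedFeature",
    "fit_univariable",
    "optimal_threshold",
    "screen_all",
]

logger = logging.getLogger(__name__)

#: |beta| beyond which a maximum-likelihood logistic fit is treated as
#: (quasi-)separated and the covariate flagged degenerate
_SEPARATION_COEF_BOUND = 50.0


@dataclass(frozen=True)
class UnivariableFit:
    """Maximum-likelihood simple logistic fit of one covariate."""

    beta0: float
    beta1: float
    p_value: float
    n_used: int
    degenerate: bool = False
    reason: str | None = None


@dataclass(frozen=True)
class ScreenedFeature:
    """A covariate retained by step-1 screening.

    ``threshold`` is the optimal classification cutpoint T on the fitted
    probability scale; ``cutoff_raw`` is the equivalent covariate-scale
    cutoff (logit(T) − β₀)/β₁.
    """

    endpoint: str
    parameter: str
    segment: str | None
    phase: str | None
    beta0: float
    beta1: float
    threshold: float
    cutoff_raw: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must lie strictly in (0,1), got {self.threshold}")
        if not math.isfinite(self.beta1) or self.beta1 == 0.0:
            raise ValueError("beta1 must be finite and nonzero for a selected feature")

    @property
    def key(self) -> str:
        """Stable identity string used as a matrix column name."""
        if self.segment is None:
            return self.parameter
        return f"{self.parameter}|{self.segment}|{self.phase}"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenedFeature":
        return cls(**d)


def fit_univariable(x: np.ndarray, y: np.ndarray) -> UnivariableFit:
    """Fit P(y=1) = φ(β₀ + β₁x) by maximum likelihood on complete cases.

    Returns the estimates with a two-sided Wald p-value for β₁.  Covariates
    exhibiting (quasi-)complete separation, failing to converge, or leaving
    fewer than two complete cases in either outcome class are flagged
    ``degenerate`` rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x)
    x, y = x[keep], y[keep]
    n = x.size

    def _degenerate(reason: str) -> UnivariableFit:
        return UnivariableFit(math.nan, math.nan, math.nan, n, degenerate=True, reason=reason)

    if n == 0:
        return _degenerate("all values missing")
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        return _degenerate("fewer than 2 complete cases in an outcome class")
    if np.ptp(x) == 0:
        return _degenerate("constant covariate")

    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # PerfectSeparationError and numerical failures
        return _degenerate(f"fit failed: {type(exc).__name__}")
    beta0, beta1 = res.params
    if not res.mle_retvals.get("converged", False):
        return _degenerate("did not converge")
    if max(abs(beta0), abs(beta1)) > _SEPARATION_COEF_BOUND:
        return _degenerate("quasi-complete separation")
    return UnivariableFit(float(beta0), float(beta1), float(res.pvalues[1]), n)


def youden_threshold(probs: np.ndarray, y: np.ndarray, criterion: str = "youden") -> float:
    """Optimal cutpoint on fitted probabilities.

    Classification is positive when the fitted probability exceeds the
    cutpoint.  The objective (Youden's J = sens + spec − 1, or accuracy) is
    piecewise constant between consecutive distinct probabilities; the
    midpoint of the (first) maximizing interval is returned.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=bool)
    uniq = np.unique(probs)
    if uniq.size < 2:
        raise ValueError("fitted probabilities are constant; no threshold exists")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes are required")

    # candidate intervals: (0,u1), (u1,u2), ..., (um,1); the objective is
    # constant on each.  For t in interval i, "prob > t" means the prob's
    # rank among uniq values is >= i, so tp/tn follow from suffix sums of
    # per-value class histograms.
    edges = np.concatenate(([0.0], uniq, [1.0]))
    idx = np.searchsorted(uniq, probs)
    m = uniq.size
    pos_hist = np.bincount(idx[y], minlength=m)
    neg_hist = np.bincount(idx[~y], minlength=m)
    # suffix[i] = count of probs with rank >= i, for i = 0..m
    tp = np.concatenate((np.cumsum(pos_hist[::-1])[::-1], [0]))
    fp = np.concatenate((np.cumsum(neg_hist[::-1])[::-1], [0]))
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    if criterion == "youden":
        obj = sens + spec - 1.0
    elif criterion == "accuracy":
        obj = (tp + (n_neg - fp)) / y.size
    else:
        raise ValueError(f"unknown threshold criterion: {criterion!r}")
    best = obj.max()
    is_best = np.isclose(obj, best)
    # merge the first run of contiguous maximizing intervals
    start = int(np.argmax(is_best))
    stop = start
    while stop + 1 < is_best.size and is_best[stop + 1]:
        stop += 1
    lo, hi = edges[start], edges[stop + 1]
    return float((lo + hi) / 2.0)


def optimal_threshold(
    fit: UnivariableFit, x: np.ndarray, y: np.ndarray, criterion: str = "youden"
) -> float:
    """Optimal probability threshold T for a fitted univariable model."""
    if fit.degenerate:
        raise ValueError(f"cannot compute a threshold for a degenerate fit ({fit.reason})")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=bool)
    keep = np.isfinite(x)
    probs = expit(fit.beta0 + fit.beta1 * x[keep])
    return youden_threshold(probs, y[keep], criterion=criterion)


def candidate_covariates() -> list[tuple[str, str | None, str | None]]:
    """All (parameter, segment, phase) candidates plus patient-level ΔWMSI."""
    cands: list[tuple[str, str | None, str | None]] = [
        (param, seg, phase)
        for param in PARAMETER_NAMES
        for seg in SEGMENTS
        for phase in PHASES
    ]
    cands.append(("delta_wmsi", None, None))
    return cands


def screen_all(
    cohort: Cohort,
    endpoint: str,
    alpha: float = 0.05,
    threshold_criterion: str = "youden",
) -> list[ScreenedFeature]:
    """Screen every candidate covariate against ``endpoint``.

    Fits one simple logistic regression per (parameter, segment, phase)
    combination — separately per segment, since deformation amplitudes are
    location-dependent — and retains covariates with p < ``alpha``.  ΔWMSI
    always enters as a candidate.  An empty selection is a valid outcome.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    y = cohort.labels(endpoint)
    selected: list[ScreenedFeature] = []
    for param, seg, phase in candidate_covariates():
        x = cohort.covariate(param, seg, phase) if seg is not None else cohort.delta_wmsi()
        fit = fit_univariable(x, y)
        if fit.degenerate:
            logger.info("excluded %s|%s|%s for %s: %s", param, seg, phase, endpoint, fit.reason)
            continue
        if not (fit.p_value < alpha):
            continue
        try:
            t = optimal_threshold(fit, x, y, criterion=threshold_criterion)
        except ValueError as exc:
            logger.info("excluded %s|%s|%s for %s: %s", param, seg, phase, endpoint, exc)
            continue
        cutoff_raw = float((logit(t) - fit.beta0) / fit.beta1)
        selected.append(
            ScreenedFeature(
                endpoint=endpoint,
                parameter=param,
                segment=seg,
                phase=phase,
                beta0=fit.beta0,
                beta1=fit.beta1,
                threshold=t,
                cutoff_raw=cutoff_raw,
                p_value=fit.p_value,
            )
        )
    logger.info("endpoint %s: %d covariates retained at alpha=%g", endpoint, len(selected), alpha)
    return selected
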