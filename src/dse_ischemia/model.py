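"""Step 3 — stepwise logistic combination and the full study pipeline.

The rescaled complete matrix is combined into one logistic classifier per
endpoint (any stenosis per patient, and LAD/LCX/RCA separately) by
bidirectional stepwise selection, AIC-guided by default, starting from the
intercept-only model.  Because every rescaled covariate is a nonnegative
"distance from its own classification threshold", the final model acts
like a weighted vote over single-covariate classifiers; a missing
measurement contributes a zero vote and never blocks prediction.

:func:`run_study` reproduces the study design: all four endpoint models
are constructed on the training ("test") cohort only and then evaluated on
both the training and the held-out validation cohort, alongside the visual
wall-motion comparator, yielding a per-group × per-method performance
table.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .config import StudyConfig
from .evaluation import DiagnosticPerformance, performance
from .rescaling import RescaledMatrix, build_matrix, rescale
from .screening import ScreenedFeature, screen_all, youden_threshold
from .synthetic import Cohort, PatientRecord

__all__ = [
    "FittedEndpointModel",
    "stepwise_fit",
    "predict_proba",
    "classify",
    "run_study",
    "StudyReport",
    "ENDPOINTS",
]

logger = logging.getLogger(__name__)

ENDPOINTS: tuple[str, ...] = ("any", "LAD", "LCX", "RCA")

#: |coef| beyond which the refitted final model is treated as separated
_SEPARATION_BOUND = 25.0


@dataclass(frozen=True)
class FittedEndpointModel:
    """A fitted per-endpoint classifier.

    ``screened_features`` is the full step-1 selection; ``selected`` the
    stepwise-retained subset (by feature key); ``coefficients`` maps each
    selected key to its weight on the rescaled scale.
    """

    endpoint: str
    screened_features: tuple[ScreenedFeature, ...]
    selected: tuple[str, ...]
    intercept: float
    coefficients: Mapping[str, float]
    decision_threshold: float = 0.5
    strict_linear_branch: bool = False
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        screened_keys = {f.key for f in self.screened_features}
        if not set(self.selected) <= screened_keys:
            raise ValueError("selected features must be a subset of screened features")
        values = [self.intercept, *self.coefficients.values()]
        if not all(np.isfinite(values)):
            raise ValueError("model coefficients must be finite")

    def _selected_features(self) -> list[ScreenedFeature]:
        by_key = {f.key: f for f in self.screened_features}
        return [by_key[k] for k in self.selected]

    def to_json(self, path) -> None:
        payload = {
            "schema_version": 1,
            "endpoint": self.endpoint,
            "screened_features": [f.to_dict() for f in self.screened_features],
            "selected": list(self.selected),
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "decision_threshold": self.decision_threshold,
            "strict_linear_branch": self.strict_linear_branch,
            "provenance": dict(self.provenance),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "FittedEndpointModel":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            endpoint=d["endpoint"],
            screened_features=tuple(ScreenedFeature.from_dict(f) for f in d["screened_features"]),
            selected=tuple(d["selected"]),
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            decision_threshold=d["decision_threshold"],
            strict_linear_branch=d.get("strict_linear_branch", False),
            provenance=d.get("provenance", {}),
        )


def _logit_aic(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray | None]:
    """AIC and params of a logistic fit; (inf, None) on failure."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception:
        return (np.inf, None)
    if not res.mle_retvals.get("converged", False):
        return (np.inf, None)
    return (float(res.aic), np.asarray(res.params))


def _newton_logit_aic(y: np.ndarray, X: np.ndarray) -> float:
    """AIC of a logistic ML fit via damped Newton iteration.

    Used only inside the stepwise AIC sweep, where thousands of small
    candidate fits are compared; diverging (separated) candidates return
    inf, matching the behaviour of a failed ML fit.
    """
    k = X.shape[1]
    beta = np.zeros(k)
    nll_old = np.inf
    for _ in range(60):
        eta = X @ beta
        p = expit(eta)
        nll = -np.sum(y * eta - np.logaddexp(0.0, eta))
        grad = X.T @ (p - y)
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X + 1e-10 * np.eye(k)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return np.inf
        # step halving keeps the iteration monotone
        scale = 1.0
        for _half in range(20):
            trial = beta - scale * step
            eta_t = X @ trial
            nll_t = -np.sum(y * eta_t - np.logaddexp(0.0, eta_t))
            if nll_t <= nll + 1e-12:
                break
            scale *= 0.5
        beta = beta - scale * step
        if abs(nll_old - nll_t) < 1e-9 and np.max(np.abs(grad)) < 1e-5:
            break
        nll_old = nll_t
    else:
        return np.inf
    if np.max(np.abs(beta)) > 100.0:
        return np.inf  # (quasi-)separated candidate
    return 2.0 * k + 2.0 * nll_t


def _design(values: np.ndarray, cols: Sequence[int]) -> np.ndarray:
    n = values.shape[0]
    if not cols:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), values[:, list(cols)]])


def _stepwise_aic(values: np.ndarray, y: np.ndarray) -> list[int]:
    """Bidirectional stepwise selection by AIC from the empty model."""
    k = values.shape[1]
    current: list[int] = []
    current_aic = _newton_logit_aic(y, _design(values, current))
    for _ in range(2 * k + 20):
        best_move, best_aic = None, current_aic
        for j in range(k):
            if j in current:
                trial = [c for c in current if c != j]
            else:
                trial = current + [j]
            aic = _newton_logit_aic(y, _design(values, trial))
            if aic < best_aic - 1e-9:
                best_move, best_aic = trial, aic
        if best_move is None:
            break
        current, current_aic = best_move, best_aic
    return sorted(current)


def _stepwise_pvalue(
    values: np.ndarray, y: np.ndarray, p_enter: float = 0.05, p_remove: float = 0.10
) -> list[int]:
    """Classic forward-entry / backward-removal stepwise by Wald p-values."""
    k = values.shape[1]
    current: list[int] = []
    for _ in range(2 * k + 20):
        changed = False
        # forward: add the most significant candidate below p_enter
        best_j, best_p = None, p_enter
        for j in range(k):
            if j in current:
                continue
            X = _design(values, current + [j])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(y, X).fit(disp=0, maxiter=100)
                p = float(res.pvalues[-1])
            except Exception:
                continue
            if p < best_p:
                best_j, best_p = j, p
        if best_j is not None:
            current.append(best_j)
            changed = True
        # backward: drop the least significant retained term above p_remove
        if current:
            X = _design(values, current)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(y, X).fit(disp=0, maxiter=100)
                pvals = np.asarray(res.pvalues[1:])
                worst = int(np.argmax(pvals))
                if pvals[worst] > p_remove:
                    current.pop(worst)
                    changed = True
            except Exception:
                pass
        if not changed:
            break
    return sorted(current)


def stepwise_fit(
    matrix: RescaledMatrix,
    y: np.ndarray | Sequence[bool],
    endpoint: str,
    criterion: str = "aic",
    decision_threshold: float = 0.5,
    strict_linear_branch: bool = False,
    provenance: Mapping[str, object] | None = None,
) -> FittedEndpointModel:
    """Stepwise logistic regression on the rescaled complete matrix.

    Starts from the intercept-only model and selects bidirectionally (AIC
    by default, forward-0.05/backward-0.10 p-value stepping optionally),
    then refits maximum-likelihood coefficients on the final set.  If the
    final refit shows (quasi-)separation the coefficients are obtained
    from an L2-penalized refit instead, with a logged warning.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("endpoint labels contain a single class")
    values = matrix.values
    keys = list(matrix.frame.columns)

    if criterion == "aic":
        chosen = _stepwise_aic(values, y)
    elif criterion == "pvalue":
        chosen = _stepwise_pvalue(values, y)
    else:
        raise ValueError(f"unknown stepwise criterion: {criterion!r}")

    X = _design(values, chosen)
    aic, params = _logit_aic(y, X)
    if params is None or np.max(np.abs(params)) > _SEPARATION_BOUND:
        logger.warning(
            "endpoint %s: separation in final model; using penalized refit", endpoint
        )
        from sklearn.linear_model import LogisticRegression

        if chosen:
            lr = LogisticRegression(C=10.0, solver="lbfgs", max_iter=1000)
            lr.fit(values[:, chosen], y)
            params = np.concatenate(([lr.intercept_[0]], lr.coef_[0]))
        else:
            prev = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
            params = np.array([np.log(prev / (1 - prev))])

    selected_keys = tuple(keys[j] for j in chosen)
    coefficients = {k: float(b) for k, b in zip(selected_keys, params[1:])}
    logger.info(
        "endpoint %s: stepwise retained %d of %d screened covariates",
        endpoint,
        len(selected_keys),
        len(keys),
    )
    return FittedEndpointModel(
        endpoint=endpoint,
        screened_features=matrix.features,
        selected=selected_keys,
        intercept=float(params[0]),
        coefficients=coefficients,
        decision_threshold=decision_threshold,
        strict_linear_branch=strict_linear_branch,
        provenance=dict(provenance or {}),
    )


def _intercept_only_model(
    endpoint: str, y: np.ndarray, decision_threshold: float, provenance: Mapping[str, object]
) -> FittedEndpointModel:
    """Fallback when screening selects nothing: predict the prevalence."""
    prev = float(np.clip(np.mean(y), 1e-6, 1 - 1e-6))
    return FittedEndpointModel(
        endpoint=endpoint,
        screened_features=(),
        selected=(),
        intercept=float(np.log(prev / (1 - prev))),
        coefficients={},
        decision_threshold=decision_threshold,
        provenance=dict(provenance),
    )


def _rescaled_matrix_for(model: FittedEndpointModel, cohort: Cohort) -> np.ndarray:
    feats = model._selected_features()
    if not feats:
        return np.zeros((len(cohort), 0))
    cols = [
        rescale(
            cohort.covariate(f.parameter, f.segment, f.phase),
            f,
            strict_linear_branch=model.strict_linear_branch,
        )
        for f in feats
    ]
    return np.column_stack(cols)


def predict_proba(
    model: FittedEndpointModel, patient: PatientRecord | Cohort
) -> float | np.ndarray:
    """Predicted endpoint probability φ(intercept + Σ wᵢ·x̃ᵢ).

    Raw covariates are rescaled with the model's stored step-1 fits;
    missing values contribute 0, so prediction never fails on incomplete
    patients (a patient with everything missing gets φ(intercept)).
    """
    if isinstance(patient, Cohort):
        X = _rescaled_matrix_for(model, patient)
        w = np.array([model.coefficients[k] for k in model.selected])
        return expit(model.intercept + X @ w)
    feats = model._selected_features()
    by_key: dict[str, float] = {}
    for m in patient.measurements:
        by_key[f"{m.parameter}|{m.segment}|{m.phase}"] = (
            np.nan if m.value is None else m.value
        )
    lin = model.intercept
    for f in feats:
        raw = patient.delta_wmsi if f.parameter == "delta_wmsi" else by_key.get(f.key, np.nan)
        lin += model.coefficients[f.key] * rescale(
            raw, f, strict_linear_branch=model.strict_linear_branch
        )
    return float(expit(lin))


def classify(model: FittedEndpointModel, patient: PatientRecord | Cohort):
    """Binary call: predicted probability ≥ decision threshold (inclusive)."""
    proba = predict_proba(model, patient)
    return proba >= model.decision_threshold


@dataclass(frozen=True)
class StudyReport:
    """Per-group × per-method diagnostic performance table plus the models."""

    rows: pd.DataFrame  # columns: group, method, tp.., sensitivity.., npv_hi
    models: Mapping[str, FittedEndpointModel]
    config: StudyConfig

    METHOD_LABELS = {
        "visual": "Visual wall motion analysis",
        "any": "Model for at least one stenosis per patient",
        "LAD": "LAD model",
        "LCX": "LCX model",
        "RCA": "RCA model",
    }

    def performance_of(self, group: str, method: str) -> DiagnosticPerformance:
        row = self.rows[(self.rows["group"] == group) & (self.rows["method"] == method)]
        if len(row) != 1:
            raise KeyError(f"no unique report row for ({group}, {method})")
        r = row.iloc[0]
        return DiagnosticPerformance(
            tp=int(r["tp"]), fp=int(r["fp"]), tn=int(r["tn"]), fn=int(r["fn"]),
            ci_method=self.config.ci_method,
        )

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.6f")

    def to_text(self) -> str:
        """Human-readable performance table (method × group rows)."""
        lines = [
            "Performance of multiparametric models and visual wall motion analysis",
            "",
            f"{'Method':<46}{'Group':<12}{'Sens % (95% CI)':<22}"
            f"{'Spec % (95% CI)':<22}{'PPV % (95% CI)':<22}{'NPV % (95% CI)':<22}",
        ]
        for method in self.METHOD_LABELS:
            for group in ("test", "validation"):
                sel = self.rows[
                    (self.rows["group"] == group) & (self.rows["method"] == method)
                ]
                if sel.empty:
                    continue
                r = sel.iloc[0]

                def cell(name: str) -> str:
                    v, lo, hi = r[name], r[f"{name}_lo"], r[f"{name}_hi"]
                    if pd.isna(v):
                        return "undefined"
                    return f"{v:.1f} ({lo:.1f}; {hi:.1f})"

                lines.append(
                    f"{self.METHOD_LABELS[method]:<46}{group:<12}"
                    f"{cell('sensitivity'):<22}{cell('specificity'):<22}"
                    f"{cell('ppv'):<22}{cell('npv'):<22}"
                )
        return "\n".join(lines) + "\n"


def _check_schema(train: Cohort, validation: Cohort) -> None:
    if not train.values.columns.equals(validation.values.columns):
        raise ValueError("train and validation cohorts have different measurement schemas")
    if set(train.patients.columns) != set(validation.patients.columns):
        raise ValueError("train and validation cohorts have different patient schemas")


def run_study(
    train: Cohort, validation: Cohort, config: StudyConfig | None = None
) -> StudyReport:
    """Construct all endpoint models on ``train`` and evaluate on both cohorts.

    Screening, rescaling and stepwise fitting use the training cohort
    only; the validation cohort is touched exclusively at prediction time.
    The visual wall-motion comparator is evaluated with the same metrics
    machinery against the any-stenosis label.
    """
    config = config or StudyConfig()
    _check_schema(train, validation)
    provenance = {"config_hash": config.config_hash(), "seed": config.seed}

    models: dict[str, FittedEndpointModel] = {}
    for endpoint in ENDPOINTS:
        y = train.labels(endpoint).astype(float)
        screened = screen_all(
            train, endpoint, alpha=config.alpha, threshold_criterion=config.threshold_criterion
        )
        if not screened:
            models[endpoint] = _intercept_only_model(
                endpoint, y, config.decision_threshold, provenance
            )
            continue
        matrix = build_matrix(train, screened, strict_linear_branch=config.strict_linear_branch)
        model = stepwise_fit(
            matrix,
            y,
            endpoint,
            criterion=config.stepwise_criterion,
            decision_threshold=config.decision_threshold,
            strict_linear_branch=config.strict_linear_branch,
            provenance=provenance,
        )
        if config.decision_threshold_mode == "youden_train":
            probs = predict_proba(model, train)
            try:
                t = youden_threshold(np.asarray(probs), train.labels(endpoint))
            except ValueError:
                t = config.decision_threshold
            model = FittedEndpointModel(
                **{**model.__dict__, "decision_threshold": float(t)}
            )
        models[endpoint] = model

    rows = []
    for group_name, cohort in (("test", train), ("validation", validation)):
        perf_visual = performance(
            cohort.patients["visual_positive"].to_numpy(dtype=bool),
            cohort.labels("any"),
            ci_method=config.ci_method,
        )
        rows.append({"group": group_name, "method": "visual", **perf_visual.as_row()})
        for endpoint in ENDPOINTS:
            pred = classify(models[endpoint], cohort)
            perf = performance(pred, cohort.labels(endpoint), ci_method=config.ci_method)
            rows.append({"group": group_name, "method": endpoint, **perf.as_row()})
    frame = pd.DataFrame(rows)
    return StudyReport(rows=frame, models=models, config=config)
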