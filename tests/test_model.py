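"""Stepwise combination, prediction and the end-to-end study run."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from dse_ischemia import (
    CohortConfig,
    FittedEndpointModel,
    RescaledMatrix,
    ScreenedFeature,
    StudyConfig,
    classify,
    predict_proba,
    run_study,
    simulate_cohort,
    stepwise_fit,
)


def make_matrix(values, keys=None, rng=None):
    keys = keys or [f"f{j}" for j in range(values.shape[1])]
    feats = tuple(
        ScreenedFeature("any", k, None, None, 0.0, 1.0, 0.5, 0.0, 0.01) for k in keys
    )
    frame = pd.DataFrame(values, columns=[f.key for f in feats])
    return RescaledMatrix(frame=frame, features=feats)


class TestStepwiseFit:
    def test_informative_feature_retained(self, rng):
        n = 400
        x = rng.random((n, 5))
        y = rng.random(n) < expit(-2.0 + 4.0 * x[:, 0])
        model = stepwise_fit(make_matrix(x), y, "any")
        assert "f0" in model.selected
        assert model.coefficients["f0"] > 0

    def test_duplicated_feature_kept_once(self, rng):
        n = 300
        base = rng.random(n)
        x = np.column_stack([base, base, rng.random(n)])
        y = rng.random(n) < expit(-2.0 + 4.0 * base)
        model = stepwise_fit(make_matrix(x), y, "any")
        assert ("f0" in model.selected) != ("f1" in model.selected)

    def test_null_features_rarely_kept(self, rng):
        kept = 0
        for _ in range(20):
            x = rng.random((200, 4))
            y = rng.random(200) < 0.5
            kept += len(stepwise_fit(make_matrix(x), y, "any").selected)
        assert kept / (20 * 4) < 0.25  # AIC keeps some noise, but not most

    def test_single_class_rejected(self, rng):
        x = rng.random((50, 2))
        with pytest.raises(ValueError):
            stepwise_fit(make_matrix(x), np.ones(50, bool), "any")

    def test_pvalue_criterion_available(self, rng):
        n = 400
        x = rng.random((n, 4))
        y = rng.random(n) < expit(-2.0 + 4.0 * x[:, 0])
        model = stepwise_fit(make_matrix(x), y, "any", criterion="pvalue")
        assert "f0" in model.selected


class TestPrediction:
    def _model(self):
        f = ScreenedFeature("any", "systolic_strain", "apical septal", "stress",
                            -5.0, 0.25, 0.4, 0.0, 0.001)
        return FittedEndpointModel(
            endpoint="any", screened_features=(f,), selected=(f.key,),
            intercept=-1.0, coefficients={f.key: 2.5},
        )

    def test_all_missing_gives_intercept(self):
        cohort = simulate_cohort(CohortConfig(n_patients=5, seed=1))
        cohort.values.loc[:, :] = np.nan
        probs = predict_proba(self._model(), cohort)
        assert np.allclose(probs, expit(-1.0))

    def test_hand_computed_linear_combination(self):
        from dse_ischemia import rescale

        cohort = simulate_cohort(
            CohortConfig(n_patients=3, missing_rate_rest=0.0, missing_rate_stress=0.0, seed=6)
        )
        model = self._model()
        f = model.screened_features[0]
        raw = cohort.covariate(f.parameter, f.segment, f.phase)
        expected = expit(-1.0 + 2.5 * rescale(raw, f))
        assert np.allclose(predict_proba(model, cohort), expected)

    def test_record_and_cohort_prediction_agree(self):
        cohort = simulate_cohort(CohortConfig(n_patients=6, seed=44))
        model = self._model()
        vec = predict_proba(model, cohort)
        for i, rec in enumerate(cohort):
            assert predict_proba(model, rec) == pytest.approx(vec[i])

    def test_probability_in_open_interval(self, small_cohort):
        probs = predict_proba(self._model(), small_cohort)
        assert ((probs > 0) & (probs < 1)).all()

    def test_classify_threshold_convention(self):
        model = FittedEndpointModel(
            endpoint="any", screened_features=(), selected=(), intercept=0.0,
            coefficients={}, decision_threshold=0.5,
        )
        cohort = simulate_cohort(CohortConfig(n_patients=3, seed=1))
        # phi(0) = 0.5 equals the threshold: >= convention gives positive
        assert classify(model, cohort).all()
        strict = FittedEndpointModel(
            endpoint="any", screened_features=(), selected=(), intercept=0.0,
            coefficients={}, decision_threshold=1.0,
        )
        assert not classify(strict, cohort).any()

    def test_json_round_trip(self, tmp_path):
        model = self._model()
        path = tmp_path / "m.json"
        model.to_json(path)
        loaded = FittedEndpointModel.from_json(path)
        assert loaded == model
        # and serialization is byte-stable
        loaded.to_json(tmp_path / "m2.json")
        assert path.read_bytes() == (tmp_path / "m2.json").read_bytes()

    def test_selected_subset_enforced(self):
        with pytest.raises(ValueError):
            FittedEndpointModel(
                endpoint="any", screened_features=(), selected=("ghost",),
                intercept=0.0, coefficients={"ghost": 1.0},
            )


@pytest.fixture(scope="module")
def small_study():
    cfg = StudyConfig(seed=5)
    train = simulate_cohort(
        CohortConfig(n_patients=100, seed=cfg.train.seed), group="test"
    )
    valid = simulate_cohort(
        CohortConfig(n_patients=70, prevalence_any=0.657, seed=cfg.validation.seed),
        group="validation",
    )
    return run_study(train, valid, cfg)


class TestRunStudy:
    def test_report_shape(self, small_study):
        rows = small_study.rows
        assert set(rows["group"]) == {"test", "validation"}
        assert set(rows["method"]) == {"visual", "any", "LAD", "LCX", "RCA"}
        assert len(rows) == 10

    def test_train_accuracy_exceeds_validation(self, small_study):
        """The apparent-performance optimism of models evaluated on their
        own construction data."""
        j_train = small_study.performance_of("test", "any").youden_j
        j_valid = small_study.performance_of("validation", "any").youden_j
        assert j_train > j_valid

    def test_identical_cohorts_identical_rows(self):
        cohort = simulate_cohort(CohortConfig(n_patients=90, seed=23))
        report = run_study(cohort, cohort, StudyConfig(seed=3))
        test_rows = report.rows[report.rows["group"] == "test"].drop(columns="group")
        val_rows = report.rows[report.rows["group"] == "validation"].drop(columns="group")
        pd.testing.assert_frame_equal(
            test_rows.reset_index(drop=True), val_rows.reset_index(drop=True)
        )

    def test_text_report_renders(self, small_study):
        text = small_study.to_text()
        assert "Visual wall motion analysis" in text
        assert "LCX model" in text

    def test_schema_mismatch_rejected(self, small_cohort):
        other = simulate_cohort(CohortConfig(n_patients=10, seed=2))
        other.values.drop(columns=[other.values.columns[0]], inplace=True)
        with pytest.raises(ValueError):
            run_study(small_cohort, other, StudyConfig())
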