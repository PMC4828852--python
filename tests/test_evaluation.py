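"""Diagnostic accuracy metrics, CI overlap rule, reproducibility statistic."""

import math

import numpy as np
import pytest

from dse_ischemia import (
    DiagnosticPerformance,
    compare_by_ci_overlap,
    mean_percentage_difference,
    performance,
    printed_percentage,
)


class TestPerformance:
    def test_worked_counts(self):
        p = DiagnosticPerformance(tp=9, fn=1, tn=8, fp=2)
        assert p.sensitivity.value == pytest.approx(90.0)
        assert p.specificity.value == pytest.approx(80.0)
        assert p.ppv.value == pytest.approx(81.8, abs=0.05)
        assert p.npv.value == pytest.approx(88.9, abs=0.05)

    def test_perfect_predictions(self):
        labels = np.array([True] * 5 + [False] * 5)
        p = performance(labels, labels)
        for m in (p.sensitivity, p.specificity, p.ppv, p.npv):
            assert m.value == 100.0

    def test_wilson_ci_worked_example(self):
        p = DiagnosticPerformance(tp=9, fn=1, tn=5, fp=5)
        lo, hi = p.sensitivity.ci
        assert lo == pytest.approx(59.6, abs=0.1)
        assert hi == pytest.approx(98.2, abs=0.1)

    def test_ci_contains_point_estimate(self, rng):
        for _ in range(200):
            counts = rng.integers(0, 40, size=4)
            p = DiagnosticPerformance(*map(int, counts))
            for name in ("sensitivity", "specificity", "ppv", "npv"):
                m = getattr(p, name)
                if m.defined:
                    assert m.lower - 1e-9 <= m.value <= m.upper + 1e-9
                    assert 0.0 <= m.lower and m.upper <= 100.0

    def test_undefined_ppv_flagged_not_zero(self):
        p = DiagnosticPerformance(tp=0, fp=0, tn=10, fn=5)
        assert not p.ppv.defined
        assert math.isnan(p.ppv.value)

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (10, 40, 160):
            p = DiagnosticPerformance(tp=int(0.8 * n), fn=n - int(0.8 * n), tn=1, fp=1)
            m = p.sensitivity
            widths.append(m.upper - m.lower)
        assert widths[0] > widths[1] > widths[2]

    def test_bayes_identity(self, rng):
        """PPV from counts equals sens·prev / (sens·prev + (1−spec)(1−prev))."""
        for _ in range(200):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 50, size=4))
            p = DiagnosticPerformance(tp, fp, tn, fn)
            sens, spec = p.sensitivity.value / 100, p.specificity.value / 100
            prev = (tp + fn) / (tp + fp + tn + fn)
            expected = 100 * sens * prev / (sens * prev + (1 - spec) * (1 - prev))
            assert p.ppv.value == pytest.approx(expected, abs=1e-9)

    def test_label_swap_duality(self, rng):
        """Swapping predictions and labels swaps sens↔ppv and spec↔npv."""
        pred = rng.random(100) < 0.4
        lab = rng.random(100) < 0.5
        a, b = performance(pred, lab), performance(lab, pred)
        assert a.sensitivity.value == pytest.approx(b.ppv.value)
        assert a.specificity.value == pytest.approx(b.npv.value)

    def test_clopper_pearson_available(self):
        p = DiagnosticPerformance(tp=9, fn=1, tn=5, fp=5, ci_method="clopper-pearson")
        lo, hi = p.sensitivity.ci
        assert lo < 59.6 and hi > 98.2  # wider than Wilson

    def test_input_validation(self):
        with pytest.raises(ValueError):
            performance([True], [True])  # single class
        with pytest.raises(ValueError):
            performance([], [])
        with pytest.raises(ValueError):
            DiagnosticPerformance(tp=-1, fp=0, tn=1, fn=1)


class TestCiOverlap:
    def test_paper_style_overlap_not_significant(self):
        assert not compare_by_ci_overlap((65.6, 85.2), (82.8, 96.1))

    def test_disjoint_significant(self):
        assert compare_by_ci_overlap((10, 20), (30, 40))

    def test_touching_counts_as_overlap(self):
        assert not compare_by_ci_overlap((10, 20), (20, 30))

    def test_symmetric(self, rng):
        for _ in range(50):
            a = tuple(sorted(rng.random(2)))
            b = tuple(sorted(rng.random(2)))
            assert compare_by_ci_overlap(a, b) == compare_by_ci_overlap(b, a)

    def test_malformed_interval(self):
        with pytest.raises(ValueError):
            compare_by_ci_overlap((20, 10), (0, 5))


class TestMeanPercentageDifference:
    def test_identical_pairs_zero(self):
        assert mean_percentage_difference([(3.0, 3.0), (5.0, 5.0)]) == 0.0

    def test_reproducibility_summary(self, rng):
        """Paired observer WMSI readings summarize into the expected
        mean-percentage-difference scale."""
        from dse_ischemia import ReproducibilityResult

        obs1 = 1.0 + rng.random(15) * 0.3
        obs2 = obs1 * (1 + rng.normal(0, 0.03, 15))
        mpd = mean_percentage_difference(list(zip(obs1, obs2)))
        res = ReproducibilityResult(
            parameter_family="WMSI", phase="rest", mode="inter",
            mean_percentage_difference=mpd, n_pairs=15,
        )
        assert 0.0 <= res.mean_percentage_difference < 0.15

    @pytest.mark.parametrize("pair", [(11.0, 9.0), (9.0, 11.0)])
    def test_order_invariant(self, pair):
        assert mean_percentage_difference([pair]) == pytest.approx(0.2)

    def test_zero_mean_pair_excluded(self):
        with pytest.warns(UserWarning):
            v = mean_percentage_difference([(1.0, -1.0), (11.0, 9.0)])
        assert v == pytest.approx(0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_percentage_difference([])


class TestPrintedPercentage:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(76, 151, 50.3), (60, 151, 39.7), (69, 105, 65.7), (0, 151, 0.0),
         (75, 151, 49.7), (36, 105, 34.3), (137, 151, 90.7), (94, 105, 89.5)],
    )
    def test_count_pairs(self, num, den, expected):
        assert printed_percentage(num, den) == expected

    def test_half_away_from_zero(self):
        assert printed_percentage(1, 16) == 6.3  # 6.25 -> 6.3, not banker's 6.2
        assert printed_percentage(3, 400) == 0.8  # 0.75 -> 0.8

    def test_denominator_positive(self):
        with pytest.raises(ValueError):
            printed_percentage(1, 0)
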