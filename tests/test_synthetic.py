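"""Synthetic cohort generator: determinism, marginals, effect structure."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from dse_ischemia import Cohort, CohortConfig, simulate_cohort, territory_of
from dse_ischemia.parameters import PARAMETERS
from dse_ischemia.segments import SEGMENTS, VESSELS, segments_of


class TestTerritoryMap:
    @pytest.mark.parametrize(
        "segment, vessel",
        [("apical septal", "LAD"), ("basal inferior", "RCA"), ("basal lateral", "LCX"),
         ("mid anterior", "LAD"), ("mid inferior", "RCA")],
    )
    def test_conventional_assignment(self, segment, vessel):
        assert territory_of(segment) == vessel

    def test_total_and_partitioning(self):
        covered = [s for v in VESSELS for s in segments_of(v)]
        assert sorted(covered) == sorted(SEGMENTS)

    def test_unknown_segment_rejected(self):
        with pytest.raises(KeyError):
            territory_of("mid posterior")

    def test_override(self):
        custom = {s: "LAD" for s in SEGMENTS}
        assert territory_of("basal inferior", custom) == "LAD"


class TestConfigValidation:
    def test_rates_bounded(self):
        with pytest.raises(ValidationError):
            CohortConfig(prevalence_any=1.2)
        with pytest.raises(ValidationError):
            CohortConfig(missing_rate_stress=-0.1)
        with pytest.raises(ValidationError):
            CohortConfig(n_patients=0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(effect_size=float("nan"))
        with pytest.raises(ValidationError):
            CohortConfig(prevalence_any=float("inf"))

    def test_vessel_probs_keys(self):
        with pytest.raises(ValidationError):
            CohortConfig(vessel_probs={"LAD": 0.5})

    def test_unknown_noise_param(self):
        with pytest.raises(ValidationError):
            CohortConfig(noise_sd_by_param={"nonexistent": 1.0})


class TestSimulateCohort:
    def test_size_and_schema(self, small_cohort):
        assert len(small_cohort) == 80
        assert small_cohort.values.shape == (80, 13 * 12 * 2)

    def test_seed_determinism(self):
        cfg = CohortConfig(n_patients=40, seed=99)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.patients, b.patients)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_different_seeds_differ(self):
        a = simulate_cohort(CohortConfig(n_patients=40, seed=1))
        b = simulate_cohort(CohortConfig(n_patients=40, seed=2))
        assert not a.values.equals(b.values)

    def test_prevalence_within_binomial_error(self):
        n, p = 10_000, 0.503
        cohort = simulate_cohort(CohortConfig(n_patients=n, prevalence_any=p, seed=5))
        share = cohort.labels("any").mean()
        assert abs(share - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_any_stenosis_is_or_of_vessels(self, small_cohort):
        flags = small_cohort.patients[list(VESSELS)].to_numpy()
        assert np.array_equal(small_cohort.labels("any"), flags.any(axis=1))

    def test_multivessel_disease_occurs(self):
        cohort = simulate_cohort(CohortConfig(n_patients=500, seed=3))
        n_vessels = cohort.patients[list(VESSELS)].sum(axis=1)
        assert (n_vessels >= 2).any() and (n_vessels == 1).any() and (n_vessels == 3).any()

    def test_missingness_rates_converge(self):
        cfg = CohortConfig(
            n_patients=900, missing_rate_rest=0.021, missing_rate_stress=0.05, seed=8
        )
        cohort = simulate_cohort(cfg)
        for phase, rate in (("rest", 0.021), ("stress", 0.05)):
            vals = cohort.values.xs(phase, level="phase", axis=1)
            observed = vals.isna().to_numpy().mean()
            n_cells = vals.size
            assert abs(observed - rate) <= 3 * np.sqrt(rate * (1 - rate) / n_cells)

    def test_zero_missingness(self):
        cfg = CohortConfig(n_patients=50, missing_rate_rest=0.0, missing_rate_stress=0.0, seed=4)
        assert not simulate_cohort(cfg).values.isna().any().any()

    def test_null_effect_no_group_difference(self):
        cohort = simulate_cohort(CohortConfig(n_patients=4000, effect_size=0.0, seed=10))
        diseased = cohort.labels("any")
        col = cohort.values[("systolic_strain", "apical septal", "stress")]
        diff = col[diseased].mean() - col[~diseased].mean()
        se = col.std() * np.sqrt(1 / diseased.sum() + 1 / (~diseased).sum())
        assert abs(diff) <= 3.5 * se
        # ... and ΔWMSI is null too
        dw = cohort.delta_wmsi()
        dw_diff = dw[diseased].mean() - dw[~diseased].mean()
        dw_se = dw.std() * np.sqrt(1 / diseased.sum() + 1 / (~diseased).sum())
        assert abs(dw_diff) <= 3.5 * dw_se

    def test_ischemic_shift_direction_and_territory(self):
        """Stress values shift the physiological way, only in diseased territories."""
        cfg = CohortConfig(n_patients=3000, effect_size=1.0, missing_rate_rest=0.0,
                           missing_rate_stress=0.0, seed=21)
        cohort = simulate_cohort(cfg)
        lad = cohort.patients["LAD"].to_numpy()
        only_lad = lad & ~cohort.patients["LCX"] & ~cohort.patients["RCA"]
        healthy = ~cohort.labels("any")
        for param, seg in [("systolic_strain", "apical septal"), ("time_to_s", "mid anterior"),
                           ("s_velocity", "basal anterior")]:
            col = cohort.values[(param, seg, "stress")]
            shift = col[lad].mean() - col[healthy].mean()
            sign = PARAMETERS[param].ischemic_sign()
            assert np.sign(shift) == sign, (param, shift)
        # an RCA-territory segment is unshifted in LAD-only disease
        col = cohort.values[("systolic_strain", "basal inferior", "stress")]
        shift = col[only_lad].mean() - col[healthy].mean()
        se = col.std() * np.sqrt(1 / only_lad.sum() + 1 / healthy.sum())
        assert abs(shift) <= 3.5 * se

    def test_wmsi_stress_elevated_in_disease(self, small_cohort):
        dw = small_cohort.delta_wmsi()
        diseased = small_cohort.labels("any")
        assert dw[diseased].mean() > dw[~diseased].mean()
        assert (small_cohort.patients[["wmsi_rest", "wmsi_stress"]] >= 1.0).all().all()
        assert (small_cohort.patients[["wmsi_rest", "wmsi_stress"]] <= 4.0).all().all()

    def test_records_round_trip(self, small_cohort):
        records = list(small_cohort)
        assert len(records) == len(small_cohort)
        rebuilt = Cohort.from_records(records)
        pd.testing.assert_frame_equal(
            rebuilt.patients, small_cohort.patients, check_dtype=False
        )
        pd.testing.assert_frame_equal(rebuilt.values, small_cohort.values)

    def test_record_consistency(self, small_cohort):
        rec = next(iter(small_cohort))
        assert rec.any_stenosis == any(rec.stenosis.values())
        assert len(rec.measurements) == 13 * 12 * 2
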