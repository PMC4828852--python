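"""Seeded synthetic dobutamine-stress-echo cohorts.

The generator emulates the tabular structure a quantitative DSE study
produces: for each patient, 13 speckle-tracking parameters measured in 12
apical-view segments at rest and peak stress, a visual wall-motion score
index (WMSI) pair, and per-vessel angiographic stenosis labels (≥50 %
stenosis of LAD/LCX/RCA).

Generative model
----------------
* Disease status is Bernoulli(``prevalence_any``); diseased patients draw
  independent per-vessel flags (``vessel_probs``) conditioned on at least
  one stenotic vessel, so single- and multi-vessel disease both occur.
* Each parameter value is Gaussian around its phase-specific healthy mean
  (rest mean + stress response), with a shared patient-segment noise
  component inducing rest-stress correlation within a segment.
* Ischemia acts only at stress and only in the territories of stenotic
  vessels: an additive shift of ``effect_size`` standard deviations in the
  physiological direction (strain blunted toward 0, times to peak
  prolonged, S' response blunted, post-systolic and positive systolic
  strain increased).
* WMSI at stress rises in diseased patients in proportion to
  ``effect_size`` (so a zero effect size yields a fully null cohort); the
  binary visual call is ΔWMSI ≥ 0.125.
* Measurements are missing completely at random per
  (segment, parameter, phase) cell, at phase-specific rates.

Everything is driven by a single integer seed; identical configurations
produce bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .derived import delta_wmsi
from .parameters import PARAMETER_NAMES, PARAMETERS, PHASES
from .segments import DEFAULT_TERRITORY, SEGMENTS, VESSELS, segments_of

__all__ = [
    "CohortConfig",
    "SegmentMeasurement",
    "PatientRecord",
    "Cohort",
    "simulate_cohort",
]

#: rest-stress correlation of measurement noise within a patient-segment
_SHARED_NOISE_FRAC = 0.3
#: extra post-systolic shortening relative to systolic strain (%, magnitude)
_PSS_EXTRA_MEAN, _PSS_EXTRA_SD = 0.8, 0.6
#: healthy WMSI variability and diseased stress response
_WMSI_REST_SD = 0.03
_WMSI_DELTA_NULL_SD = 0.08
#: diseased mean ΔWMSI and extra ΔWMSI dispersion per unit of effect_size
#: (at the default 0.8: mean 0.22 and SD 0.18, the scale of reported group
#: means); scaling both with effect_size makes a zero effect a fully null
#: cohort
_WMSI_DELTA_PER_EFFECT = 0.275
_WMSI_DELTA_SD_PER_EFFECT = 0.125
#: visual positivity criterion on ΔWMSI
VISUAL_DELTA_WMSI_CUTOFF = 0.125


class CohortConfig(BaseModel):
    """Study conditions for one simulated cohort.

    Defaults reproduce the construction ("test") cohort shape: n=151,
    any-stenosis prevalence 0.503, segment missingness 2.1 % at rest and
    5 % at stress.  :meth:`validation_default` gives the held-out cohort
    (n=105, prevalence 0.657, missingness 2.5 % / 5.2 %).
    """

    n_patients: int = Field(default=151, ge=1)
    prevalence_any: float = Field(default=0.503, ge=0.0, le=1.0)
    vessel_probs: dict[str, float] = Field(
        default_factory=lambda: {"LAD": 0.55, "LCX": 0.50, "RCA": 0.55}
    )
    effect_size: float = Field(default=0.8, ge=0.0)
    missing_rate_rest: float = Field(default=0.021, ge=0.0, le=1.0)
    missing_rate_stress: float = Field(default=0.050, ge=0.0, le=1.0)
    noise_sd_by_param: dict[str, float] = Field(default_factory=dict)
    seed: int = Field(default=0, ge=0)

    @field_validator("prevalence_any", "effect_size", "missing_rate_rest", "missing_rate_stress")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("configuration values must be finite")
        return v

    @field_validator("vessel_probs")
    @classmethod
    def _vessels(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(VESSELS):
            raise ValueError(f"vessel_probs must have exactly the keys {VESSELS}")
        for vessel, p in v.items():
            if not (math.isfinite(p) and 0.0 <= p <= 1.0):
                raise ValueError(f"vessel probability for {vessel} must be in [0,1]")
        return v

    @field_validator("noise_sd_by_param")
    @classmethod
    def _noise(cls, v: dict[str, float]) -> dict[str, float]:
        for name, mult in v.items():
            if name not in PARAMETERS:
                raise ValueError(f"unknown parameter in noise_sd_by_param: {name!r}")
            if not (math.isfinite(mult) and mult >= 0):
                raise ValueError(f"noise multiplier for {name} must be finite and >= 0")
        return v

    @model_validator(mode="after")
    def _nonzero_vessel_mass(self) -> "CohortConfig":
        if self.prevalence_any > 0 and all(p == 0 for p in self.vessel_probs.values()):
            raise ValueError("prevalence_any > 0 requires a nonzero vessel probability")
        return self

    @classmethod
    def validation_default(cls, seed: int = 1) -> "CohortConfig":
        """Held-out cohort conditions (n=105, prevalence 0.657)."""
        return cls(
            n_patients=105,
            prevalence_any=0.657,
            missing_rate_rest=0.025,
            missing_rate_stress=0.052,
            seed=seed,
        )


@dataclass(frozen=True)
class SegmentMeasurement:
    """One quantitative parameter value for one patient/segment/phase."""

    patient_id: str
    segment: str
    parameter: str
    phase: str
    value: float | None  # None = missing (uninterpretable tracking)


@dataclass(frozen=True)
class PatientRecord:
    """All measurements and labels for one patient."""

    patient_id: str
    group: str
    wmsi_rest: float
    wmsi_stress: float
    visual_positive: bool
    stenosis: Mapping[str, bool]  # per-vessel ≥50 % stenosis flags
    measurements: tuple[SegmentMeasurement, ...] = field(repr=False)

    @property
    def any_stenosis(self) -> bool:
        return any(self.stenosis.values())

    @property
    def delta_wmsi(self) -> float:
        return delta_wmsi(self.wmsi_rest, self.wmsi_stress)


class Cohort:
    """A cohort of patients with fast columnar access.

    ``patients`` is a patient-level frame (labels, WMSI); ``values`` is a
    wide frame indexed by patient with a (parameter, segment, phase)
    column MultiIndex, NaN marking missing cells.  Iterating yields
    :class:`PatientRecord` objects.
    """

    def __init__(self, patients: pd.DataFrame, values: pd.DataFrame):
        if not patients.index.equals(values.index):
            raise ValueError("patient-level and value frames must share an index")
        self.patients = patients
        self.values = values

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def group(self) -> str:
        groups = self.patients["group"].unique()
        return groups[0] if len(groups) == 1 else "mixed"

    def labels(self, endpoint: str) -> np.ndarray:
        """Binary endpoint labels: 'any' or a vessel name."""
        if endpoint == "any":
            return self.patients[list(VESSELS)].any(axis=1).to_numpy()
        if endpoint in VESSELS:
            return self.patients[endpoint].to_numpy(dtype=bool)
        raise KeyError(f"unknown endpoint: {endpoint!r}")

    def covariate(self, parameter: str, segment: str, phase: str) -> np.ndarray:
        """Raw covariate vector across patients, NaN = missing."""
        if parameter == "delta_wmsi":
            return self.delta_wmsi()
        return self.values[(parameter, segment, phase)].to_numpy(dtype=float)

    def delta_wmsi(self) -> np.ndarray:
        return (self.patients["wmsi_stress"] - self.patients["wmsi_rest"]).to_numpy()

    def __iter__(self) -> Iterator[PatientRecord]:
        cols = self.values.columns
        for pid, row in self.patients.iterrows():
            vals = self.values.loc[pid]
            measurements = tuple(
                SegmentMeasurement(
                    patient_id=str(pid),
                    parameter=param,
                    segment=seg,
                    phase=phase,
                    value=None if pd.isna(vals[(param, seg, phase)]) else float(vals[(param, seg, phase)]),
                )
                for (param, seg, phase) in cols
            )
            yield PatientRecord(
                patient_id=str(pid),
                group=str(row["group"]),
                wmsi_rest=float(row["wmsi_rest"]),
                wmsi_stress=float(row["wmsi_stress"]),
                visual_positive=bool(row["visual_positive"]),
                stenosis={v: bool(row[v]) for v in VESSELS},
                measurements=measurements,
            )

    @classmethod
    def from_records(cls, records: list[PatientRecord]) -> "Cohort":
        if not records:
            raise ValueError("cannot build a cohort from zero records")
        pat_rows, val_rows, index = [], [], []
        columns = pd.MultiIndex.from_tuples(
            [(m.parameter, m.segment, m.phase) for m in records[0].measurements],
            names=["parameter", "segment", "phase"],
        )
        for rec in records:
            index.append(rec.patient_id)
            pat_rows.append(
                {
                    "group": rec.group,
                    "wmsi_rest": rec.wmsi_rest,
                    "wmsi_stress": rec.wmsi_stress,
                    "visual_positive": rec.visual_positive,
                    **{v: rec.stenosis.get(v, False) for v in VESSELS},
                }
            )
            cell = {(m.parameter, m.segment, m.phase): (np.nan if m.value is None else m.value) for m in rec.measurements}
            val_rows.append([cell.get(c, np.nan) for c in columns])
        patients = pd.DataFrame(pat_rows, index=pd.Index(index, name="patient_id"))
        values = pd.DataFrame(val_rows, index=patients.index, columns=columns)
        return cls(patients, values)


def _draw_vessel_flags(
    rng: np.random.Generator, diseased: np.ndarray, probs: np.ndarray
) -> np.ndarray:
    """Per-vessel flags: independent draws conditioned on >=1 for diseased."""
    n = diseased.size
    flags = np.zeros((n, len(VESSELS)), dtype=bool)
    pending = diseased.copy()
    while pending.any():
        idx = np.flatnonzero(pending)
        draw = rng.random((idx.size, len(VESSELS))) < probs
        flags[idx] = draw
        pending[idx] = ~draw.any(axis=1)
    flags[~diseased] = False
    return flags


def simulate_cohort(
    config: CohortConfig,
    group: str = "test",
    territory_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Simulate one seeded cohort under ``config``.

    Returns a :class:`Cohort` of exactly ``config.n_patients`` patients,
    fully reproducible from ``config.seed``.
    """
    tmap = DEFAULT_TERRITORY if territory_map is None else territory_map
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_seg = len(SEGMENTS)

    diseased = rng.random(n) < config.prevalence_any
    probs = np.array([config.vessel_probs[v] for v in VESSELS])
    flags = _draw_vessel_flags(rng, diseased, probs)

    # (patient, segment) cells lying in a stenotic vessel's territory
    seg_vessel = np.zeros((n_seg, len(VESSELS)), dtype=bool)
    for j, vessel in enumerate(VESSELS):
        for seg in segments_of(vessel, tmap):
            seg_vessel[SEGMENTS.index(seg), j] = True
    affected = flags @ seg_vessel.T > 0  # (n, n_seg)

    shared = rng.standard_normal((n, n_seg))  # patient-segment noise component
    arrays: dict[str, np.ndarray] = {}
    for name in PARAMETER_NAMES:
        if name in ("post_systolic_strain", "maximal_strain"):
            continue  # built from systolic strain below
        spec = PARAMETERS[name]
        sd = spec.rest_sd * config.noise_sd_by_param.get(name, 1.0)
        means = np.array([spec.rest_mean, spec.rest_mean + spec.stress_shift])
        cell = rng.standard_normal((n, n_seg, 2))
        noise = math.sqrt(_SHARED_NOISE_FRAC) * shared[..., None] + math.sqrt(
            1 - _SHARED_NOISE_FRAC
        ) * cell
        vals = means[None, None, :] + sd * noise
        vals[..., 1] += (
            config.effect_size * spec.rest_sd * spec.ischemic_sign() * affected
        )
        if name == "positive_systolic_strain":
            vals = np.abs(vals)
        arrays[name] = vals

    # post-systolic strain: slightly deeper than systolic in health, with
    # extra post-systolic shortening (more negative) in ischemic territories
    pss_spec = PARAMETERS["post_systolic_strain"]
    extra = np.abs(
        _PSS_EXTRA_MEAN + _PSS_EXTRA_SD * rng.standard_normal((n, n_seg, 2))
    )
    pss = arrays["systolic_strain"] - extra
    pss[..., 1] += (
        config.effect_size * pss_spec.rest_sd * pss_spec.ischemic_sign() * affected
    )
    arrays["post_systolic_strain"] = pss
    sys_ = arrays["systolic_strain"]
    arrays["maximal_strain"] = np.where(np.abs(pss) > np.abs(sys_), pss, sys_)

    # visual assessment: WMSI pair and the binary visual call
    wmsi_rest = 1.0 + np.abs(_WMSI_REST_SD * rng.standard_normal(n))
    delta_mean = np.where(diseased, _WMSI_DELTA_PER_EFFECT * config.effect_size, 0.0)
    delta_sd = np.where(
        diseased,
        _WMSI_DELTA_NULL_SD + _WMSI_DELTA_SD_PER_EFFECT * config.effect_size,
        _WMSI_DELTA_NULL_SD,
    )
    delta = np.abs(delta_mean + delta_sd * rng.standard_normal(n))
    wmsi_stress = np.clip(wmsi_rest + delta, 1.0, 4.0)
    wmsi_rest = np.clip(wmsi_rest, 1.0, 4.0)
    visual_positive = (wmsi_stress - wmsi_rest) >= VISUAL_DELTA_WMSI_CUTOFF

    # MCAR missingness per (segment, parameter, phase) cell
    rates = np.array([config.missing_rate_rest, config.missing_rate_stress])
    for name in PARAMETER_NAMES:
        miss = rng.random((n, n_seg, 2)) < rates[None, None, :]
        arrays[name] = np.where(miss, np.nan, arrays[name])

    width = len(str(n))
    index = pd.Index(
        [f"{group[0].upper()}{i + 1:0{width}d}" for i in range(n)], name="patient_id"
    )
    patients = pd.DataFrame(
        {
            "group": group,
            "wmsi_rest": wmsi_rest,
            "wmsi_stress": wmsi_stress,
            "visual_positive": visual_positive,
            **{v: flags[:, j] for j, v in enumerate(VESSELS)},
        },
        index=index,
    )
    columns = pd.MultiIndex.from_tuples(
        [
            (param, seg, phase)
            for param in PARAMETER_NAMES
            for seg in SEGMENTS
            for phase in PHASES
        ],
        names=["parameter", "segment", "phase"],
    )
    stacked = np.concatenate(
        [arrays[param].reshape(n, n_seg * 2) for param in PARAMETER_NAMES], axis=1
    )
    values = pd.DataFrame(stacked, index=index, columns=columns)
    return Cohort(patients, values)
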