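"""Hand-constructed miniature cohorts for worked examples and tests.

Each fixture is a deterministic cohort of at most 10 patients exercising
one pipeline behaviour: labels independent of every covariate ("null"),
one perfectly separating covariate ("separable"), heavy missingness
("missing-heavy"), and a fully observed cohort ("complete").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parameters import PARAMETER_NAMES, PARAMETERS, PHASES
from .segments import SEGMENTS, VESSELS
from .synthetic import Cohort

__all__ = ["fixture_cohort", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("null", "separable", "missing-heavy", "complete")


def _base_cohort(n: int, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = np.random.default_rng(seed)
    index = pd.Index([f"F{i+1:02d}" for i in range(n)], name="patient_id")
    columns = pd.MultiIndex.from_tuples(
        [(p, s, ph) for p in PARAMETER_NAMES for s in SEGMENTS for ph in PHASES],
        names=["parameter", "segment", "phase"],
    )
    data = np.empty((n, len(columns)))
    for j, (param, _seg, _ph) in enumerate(columns):
        spec = PARAMETERS[param]
        data[:, j] = spec.rest_mean + spec.rest_sd * rng.standard_normal(n)
    values = pd.DataFrame(data, index=index, columns=columns)
    labels = np.arange(n) % 2 == 0  # alternating, fixed pattern
    patients = pd.DataFrame(
        {
            "group": "test",
            "wmsi_rest": 1.0,
            "wmsi_stress": np.where(labels, 1.2, 1.05),
            "visual_positive": labels,
            "LAD": labels,
            "LCX": False,
            "RCA": False,
        },
        index=index,
    )
    return patients, values


def fixture_cohort(name: str) -> Cohort:
    """Return one of the named deterministic fixtures (≤10 patients)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    patients, values = _base_cohort(10, seed=20160412)
    labels = patients["LAD"].to_numpy(dtype=bool)
    if name == "null":
        # break any label-covariate link: WMSI and visual call constant
        patients["wmsi_stress"] = 1.05
        patients["visual_positive"] = [True, False] * 5
        patients["LAD"] = [True, True, False, True, False, False, True, False, True, False]
    elif name == "separable":
        col = ("systolic_strain", "apical septal", "stress")
        values[col] = np.where(labels, -8.0, -22.0) + np.linspace(0, 0.9, 10)
    elif name == "missing-heavy":
        rng = np.random.default_rng(7)
        mask = rng.random(values.shape) < 0.5
        values = values.mask(pd.DataFrame(mask, index=values.index, columns=values.columns))
    return Cohort(patients, values)
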