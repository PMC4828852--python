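"""CSV interchange for cohorts and reports.

Two files describe a cohort:

* a long-format segment table with columns
  ``patient_id, group, segment, parameter, phase, value`` where an empty
  value cell means *missing* (never zero);
* a patient table with columns
  ``patient_id, group, wmsi_rest, wmsi_stress, visual_positive, LAD, LCX, RCA``
  with 0/1 label columns.

UTF-8, header row, dot decimal separator.  Sentinel numerics (−999,
−9999) are rejected — missingness must be encoded as an empty cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parameters import PARAMETER_NAMES, PHASES
from .segments import SEGMENTS, VESSELS
from .synthetic import Cohort

__all__ = ["write_cohort", "read_cohort"]

_SENTINELS = (-999.0, -9999.0)


def write_cohort(cohort: Cohort, segment_csv, patient_csv) -> None:
    """Write a cohort to the two-file CSV interchange format."""
    long = (
        cohort.values.stack(["parameter", "segment", "phase"], future_stack=True)
        .rename("value")
        .reset_index()
    )
    long.insert(1, "group", cohort.patients["group"].reindex(long["patient_id"]).to_numpy())
    long = long[["patient_id", "group", "segment", "parameter", "phase", "value"]]
    long = long.sort_values(["patient_id", "parameter", "segment", "phase"], kind="stable")
    long.to_csv(segment_csv, index=False, encoding="utf-8")

    pat = cohort.patients.copy()
    pat["visual_positive"] = pat["visual_positive"].astype(int)
    for v in VESSELS:
        pat[v] = pat[v].astype(int)
    cols = ["group", "wmsi_rest", "wmsi_stress", "visual_positive", *VESSELS]
    pat[cols].to_csv(patient_csv, index_label="patient_id", encoding="utf-8")


class CohortSchemaError(ValueError):
    """Raised when a cohort CSV violates the interchange schema."""


def _check_known(frame: pd.DataFrame, column: str, allowed: tuple[str, ...]) -> None:
    bad = ~frame[column].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortSchemaError(
            f"unknown {column} {frame[column].iloc[row]!r} in row {row + 2} of segment table"
        )


def read_cohort(segment_csv, patient_csv) -> Cohort:
    """Read a cohort from the two-file CSV interchange format.

    Empty value cells become missing measurements; duplicate measurement
    rows, unknown segment/parameter/phase names, non-binary label columns
    and sentinel numerics are rejected with a :class:`CohortSchemaError`.
    """
    long = pd.read_csv(segment_csv, dtype={"patient_id": str}, encoding="utf-8")
    required = {"patient_id", "group", "segment", "parameter", "phase", "value"}
    if not required <= set(long.columns):
        raise CohortSchemaError(f"segment table must have columns {sorted(required)}")
    _check_known(long, "segment", SEGMENTS)
    _check_known(long, "parameter", PARAMETER_NAMES)
    _check_known(long, "phase", PHASES)
    dup = long.duplicated(["patient_id", "segment", "parameter", "phase"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise CohortSchemaError(f"duplicate measurement row at line {row + 2} of segment table")
    vals = long["value"].to_numpy(dtype=float)
    if np.isin(vals, _SENTINELS).any():
        raise CohortSchemaError(
            "sentinel numeric found in value column; encode missing values as empty cells"
        )
    if np.isinf(vals).any():
        raise CohortSchemaError("non-finite value in segment table")

    pat = pd.read_csv(patient_csv, dtype={"patient_id": str}, encoding="utf-8")
    pat_required = {"patient_id", "group", "wmsi_rest", "wmsi_stress", *VESSELS}
    if not pat_required <= set(pat.columns):
        raise CohortSchemaError(f"patient table must have columns {sorted(pat_required)}")
    if pat["patient_id"].duplicated().any():
        raise CohortSchemaError("duplicate patient_id in patient table")
    pat = pat.set_index("patient_id")
    for v in VESSELS:
        if not pat[v].isin([0, 1]).all():
            raise CohortSchemaError(f"label column {v} must be binary 0/1")
        pat[v] = pat[v].astype(bool)
    if "visual_positive" in pat.columns:
        if not pat["visual_positive"].isin([0, 1]).all():
            raise CohortSchemaError("visual_positive must be binary 0/1")
        pat["visual_positive"] = pat["visual_positive"].astype(bool)
    else:
        pat["visual_positive"] = False
    bad_wmsi = ~pat[["wmsi_rest", "wmsi_stress"]].apply(
        lambda c: (c >= 1.0) & (c <= 4.0)
    ).all(axis=1)
    if bad_wmsi.any():
        raise CohortSchemaError(
            f"WMSI outside [1,4] for patient {pat.index[bad_wmsi][0]!r}"
        )

    unknown = set(long["patient_id"]) - set(pat.index)
    if unknown:
        raise CohortSchemaError(f"segment rows for patients missing from patient table: {sorted(unknown)[:3]}")

    wide = long.pivot_table(
        index="patient_id",
        columns=["parameter", "segment", "phase"],
        values="value",
        aggfunc="first",
        dropna=False,
    )
    columns = pd.MultiIndex.from_tuples(
        [(p, s, ph) for p in PARAMETER_NAMES for s in SEGMENTS for ph in PHASES],
        names=["parameter", "segment", "phase"],
    )
    wide = wide.reindex(index=pat.index, columns=columns)
    order = ["group", "wmsi_rest", "wmsi_stress", "visual_positive", *VESSELS]
    return Cohort(pat[order], wide)
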