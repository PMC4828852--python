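"""Step 1: univariable screening of every covariate for each endpoint.

Reads the cohorts written by 01_simulate_cohorts.py, fits one simple
logistic regression per (parameter, segment, phase) candidate — plus
ΔWMSI — against each endpoint (any stenosis, LAD, LCX, RCA), and writes
the retained covariates with their raw-scale cutoffs as a model-schema
table (variable, segment, phase, cutoff, unit) plus a JSON with the full
fitted parameters (β₀, β₁, T, p).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from dse_ischemia import read_cohort, screen_all
from dse_ischemia.model import ENDPOINTS
from dse_ischemia.parameters import PARAMETERS

parser = argparse.ArgumentParser()
parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohorts"))
parser.add_argument("--alpha", type=float, default=0.05)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

train = read_cohort(
    args.cohort_dir / "test_segments.csv", args.cohort_dir / "test_patients.csv"
)
args.out_dir.mkdir(parents=True, exist_ok=True)

all_features = {}
rows = []
for endpoint in ENDPOINTS:
    feats = screen_all(train, endpoint, alpha=args.alpha)
    all_features[endpoint] = [f.to_dict() for f in feats]
    for f in feats:
        unit = "WMSI" if f.parameter == "delta_wmsi" else PARAMETERS[f.parameter].unit
        rows.append(
            {
                "endpoint": endpoint,
                "variable": f.parameter,
                "segment": f.segment or "-",
                "phase": f.phase or "-",
                "cutoff": round(f.cutoff_raw, 2),
                "unit": unit,
                "p_value": f.p_value,
            }
        )
    print(f"endpoint {endpoint}: {len(feats)} covariates retained at alpha={args.alpha}")

with open(args.out_dir / "screened_features.json", "w", encoding="utf-8") as fh:
    json.dump(all_features, fh, indent=2, sort_keys=True)
pd.DataFrame(rows).to_csv(args.out_dir / "screened_features.csv", index=False)
print(f"screened-feature tables written to {args.out_dir}")
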