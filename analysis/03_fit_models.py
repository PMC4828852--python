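"""Steps 2-3: rescale the screened covariates and fit the stepwise models.

For each endpoint the retained covariates are transformed to rescaled
[0,1] responses (missing → 0, giving a complete matrix) and combined by
bidirectional AIC stepwise logistic regression.  Writes one model JSON
per endpoint and prints how aggressively stepwise pruned the screen.
"""

import argparse
from pathlib import Path

from dse_ischemia import StudyConfig, read_cohort, run_study

parser = argparse.ArgumentParser()
parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohorts"))
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out-dir", type=Path, default=Path("results/models"))
args = parser.parse_args()

config = StudyConfig(seed=args.seed)
train = read_cohort(
    args.cohort_dir / "test_segments.csv", args.cohort_dir / "test_patients.csv"
)
valid = read_cohort(
    args.cohort_dir / "validation_segments.csv",
    args.cohort_dir / "validation_patients.csv",
)
report = run_study(train, valid, config)
args.out_dir.mkdir(parents=True, exist_ok=True)
for endpoint, model in report.models.items():
    model.to_json(args.out_dir / f"model_{endpoint}.json")
    print(
        f"endpoint {endpoint}: {len(model.screened_features)} screened -> "
        f"{len(model.selected)} retained by stepwise"
    )
print(f"model JSONs written to {args.out_dir}")
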