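"""Evaluate all endpoint models and the visual comparator on both cohorts.

Writes the per-group × per-method performance table (sensitivity,
specificity, PPV, NPV with 95 % Wilson CIs) as CSV and as a readable text
table, and applies the CI-overlap rule to ask whether the per-patient
model differs significantly from visual wall-motion analysis in each
group.
"""

import argparse
from pathlib import Path

from dse_ischemia import StudyConfig, compare_by_ci_overlap, read_cohort, run_study

parser = argparse.ArgumentParser()
parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohorts"))
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
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
report.to_csv(args.out_dir / "performance.csv")
text = report.to_text()
(args.out_dir / "performance.txt").write_text(text, encoding="utf-8")
print(text)

for group in ("test", "validation"):
    model_perf = report.performance_of(group, "any")
    visual_perf = report.performance_of(group, "visual")
    for metric in ("sensitivity", "specificity"):
        sig = compare_by_ci_overlap(
            getattr(model_perf, metric).ci, getattr(visual_perf, metric).ci
        )
        verdict = "SIGNIFICANT (non-overlapping CIs)" if sig else "not significant (CIs overlap)"
        print(f"{group}: per-patient model vs visual, {metric}: {verdict}")
print(f"\nperformance tables written to {args.out_dir}")
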