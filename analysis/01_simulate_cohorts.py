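"""Simulate the construction and validation cohorts and write them to CSV.

The construction ("test") cohort has 151 patients with any-stenosis
prevalence 0.503 and segment missingness 2.1 % (rest) / 5.0 % (stress);
the validation cohort has 105 patients, prevalence 0.657, missingness
2.5 % / 5.2 %.  Prints the realized marginals so they can be eyeballed
against the configured conditions.
"""

import argparse
from pathlib import Path

from dse_ischemia import StudyConfig, printed_percentage, simulate_cohort, write_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out-dir", type=Path, default=Path("results/cohorts"))
args = parser.parse_args()

config = StudyConfig(seed=args.seed)
args.out_dir.mkdir(parents=True, exist_ok=True)
config.to_yaml(args.out_dir / "config.yaml")

for label, cohort_cfg in (("test", config.train), ("validation", config.validation)):
    cohort = simulate_cohort(cohort_cfg, group=label)
    write_cohort(
        cohort,
        args.out_dir / f"{label}_segments.csv",
        args.out_dir / f"{label}_patients.csv",
    )
    n = len(cohort)
    prev = printed_percentage(int(cohort.labels("any").sum()), n)
    visual = printed_percentage(int(cohort.patients["visual_positive"].sum()), n)
    miss_rest = cohort.values.xs("rest", level="phase", axis=1).isna().to_numpy().mean()
    miss_stress = cohort.values.xs("stress", level="phase", axis=1).isna().to_numpy().mean()
    print(
        f"{label}: n={n}, any-stenosis {prev}%, visual-positive {visual}%, "
        f"missing rest {100*miss_rest:.1f}% / stress {100*miss_stress:.1f}%"
    )
print(f"cohort CSVs written to {args.out_dir}")
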