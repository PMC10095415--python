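"""Descriptive statistics: BMI imputation and case/control prevalence.

Reads the simulated cohort, completes missing BMI by predictive mean
matching, tabulates per-feature prevalence with chi-squared / Fisher
comparisons for the all-ages stratum and the young bracket (<55), and
highlights the largest case/control contrasts.
"""

import argparse
from pathlib import Path

from strokeage.features import default_feature_dictionary
from strokeage.io import read_patient_table
from strokeage.stats import impute_bmi, prevalence_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results/prevalence.tsv"))
    args = parser.parse_args()

    dictionary = default_feature_dictionary()
    patients = read_patient_table(args.cohort_dir / "patients.csv", dictionary)
    completed, imputed = impute_bmi(patients, dictionary, seed=args.seed)
    print(f"imputed BMI for {len(imputed)} of {len(patients)} subjects")

    table = prevalence_table(completed, dictionary, [None, 55.0])
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)

    all_ages = table[table.bracket == "all"].copy()
    all_ages["contrast"] = all_ages.case_pct - all_ages.control_pct
    top = all_ages.reindex(all_ages.contrast.abs().sort_values(ascending=False).index)
    print(f"\nlargest case-control contrasts (all ages), of {len(table)} rows total:")
    for row in top.head(6).itertuples(index=False):
        print(
            f"  {row.feature:28s} {row.sex}  cases {row.case_pct:5.1f}%  "
            f"controls {row.control_pct:5.1f}%  ({row.test_used}, p={row.p_value:.2g})"
        )
    print(f"\nfull table written to {args.out}")


if __name__ == "__main__":
    main()
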