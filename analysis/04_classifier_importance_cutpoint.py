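"""Approach 2: bracketed classifier grid and importance-trend change-point.

Trains GLM / random-forest / XGBoost case-control classifiers for the 17
cumulative age brackets (plus the all-ages reference) per sex, compares
each bracket's feature-importance vector to the reference by cosine
similarity, and estimates the change-point of the similarity trend per
algorithm and sex. Uses the reduced tuning profile (3-fold CV, 2 random
hyperparameter draws); pass --full for the 5x5-fold, 5-draw profile.
"""

import argparse
from pathlib import Path

from strokeage.features import default_feature_dictionary
from strokeage.io import read_patient_table
from strokeage.models import CVConfig
from strokeage.pipeline import run_approach2


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/approach2"))
    parser.add_argument("--full", action="store_true",
                        help="5-fold x 5-repeat CV with 5 random draws (slow)")
    args = parser.parse_args()

    cv = CVConfig(5, 5, 5) if args.full else CVConfig(3, 1, 2)
    dictionary = default_feature_dictionary()
    patients = read_patient_table(args.cohort_dir / "patients.csv", dictionary)
    results, trend, cutpoints, errors = run_approach2(
        patients, args.out_dir, dictionary, cv=cv, seed=args.seed
    )

    n_limited = sum(1 for r in results if r.bracket.upper_age is not None)
    print(f"fitted {n_limited} age-limited models + "
          f"{len(results) - n_limited} all-ages references; {len(errors)} failures")
    print("importance-trend cut-points per algorithm and sex:")
    for (alg, sex), res in sorted(
        cutpoints.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        print(f"  {alg.value:3s} {sex.value}: {res.cutpoint:.0f} years "
              f"(Z = {res.max_statistic:.1f})")
    print(f"model grid, importances and trend written to {args.out_dir}/")


if __name__ == "__main__":
    main()
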