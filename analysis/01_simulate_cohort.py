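"""Simulate the synthetic study cohort.

Draws a seeded case/control cohort with planted young-stroke change-points
(tau_f = 53, tau_m = 52 years), writes patients.csv / diagnoses.csv /
phecode_map.csv under results/cohort/, and prints the cohort composition.
"""

import argparse
from pathlib import Path

from strokeage.io import Label, Sex
from strokeage.pipeline import run_simulate
from strokeage.simulate import SyntheticCohortConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-cases", type=int, default=3000)
    parser.add_argument("--n-controls", type=int, default=3000)
    parser.add_argument("--out-dir", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()

    config = SyntheticCohortConfig(
        n_cases=args.n_cases, n_controls=args.n_controls, sex_ratio=0.5,
        seed=args.seed,
    )
    patients, events, table = run_simulate(config, args.out_dir)

    n_f = sum(1 for p in patients if p.sex is Sex.F)
    n_case = sum(1 for p in patients if p.label is Label.case)
    young_f = sum(
        1 for p in patients
        if p.sex is Sex.F and p.label is Label.case and p.age_at_index < config.tau_f
    )
    print(f"cohort: {len(patients)} subjects ({n_case} cases), {n_f} female")
    print(f"planted cut-points: tau_f={config.tau_f}, tau_m={config.tau_m}")
    print(f"female cases below tau_f: {young_f}")
    print(f"diagnosis events: {len(events)}; phecodes: {len(table.phecodes)}")
    print(f"tables written to {args.out_dir}/")


if __name__ == "__main__":
    main()
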