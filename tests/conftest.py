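import logging

import pytest

from strokeage.features import default_feature_dictionary
from strokeage.simulate import SyntheticCohortConfig, simulate_cohort

# readers/generators log row counts at INFO; keep test output quiet
logging.getLogger("strokeage").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def dictionary():
    return default_feature_dictionary()


@pytest.fixture(scope="session")
def small_cohort():
    """One small seeded cohort shared by read-only tests."""
    config = SyntheticCohortConfig(n_cases=300, n_controls=300, sex_ratio=0.5, seed=7)
    return simulate_cohort(config)


def write_patients_csv(path, rows, feature_names=()):
    header = ["patient_id", "sex", "age_at_index", "label", "bmi", *feature_names]
    lines = [",".join(header)]
    for row in rows:
        lines.append(",".join("" if v is None else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path
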