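"""Descriptive cohort statistics: prevalence comparisons and BMI handling.

Per age bracket and sex, the prevalence of every binary clinical variable
among cases is compared with controls using Pearson's chi-squared test
(without continuity correction) when all expected cell counts are >= 5 and
Fisher's exact test (two-sided) otherwise. Raw p-values are reported with a
0.05 significance convention; a Benjamini-Hochberg column is emitted
alongside for convenience but never filters output.

BMI is dichotomized at 25 kg/m^2 (normal <= 25 < overweight). Missing
continuous BMI is completed by single-variable chained-equation imputation
with predictive mean matching (PMM): a linear model of BMI on sex, age and
the clinical features is fit on complete records, every record gets a
predicted mean, and each missing value is replaced by the median over ``m``
PMM draws, each draw sampling an observed BMI from the ``k`` complete
records with the closest predictions. Only BMI is ever missing in this
pipeline, so the chained system collapses to this single equation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureDictionary
from .io import Label, PatientRecord, Sex

logger = logging.getLogger(__name__)

BMI_OVERWEIGHT_THRESHOLD = 25.0
FISHER_EXPECTED_MIN = 5.0
ALPHA = 0.05


class DegenerateTableWarning(UserWarning):
    """A 2x2 table has a zero row or column margin; p is reported as 1."""


@dataclass(frozen=True)
class PrevalenceTest:
    test_used: str  # "chi2" | "fisher" | "degenerate"
    statistic: float | None
    p_value: float


def compare_prevalence(a: int, b: int, c: int, d: int) -> PrevalenceTest:
    """Compare exposure prevalence between cases and controls.

    Parameters are the 2x2 table cells: ``a`` exposed cases, ``b`` unexposed
    cases, ``c`` exposed controls, ``d`` unexposed controls. Chooses
    Pearson's chi-squared (no continuity correction) when every expected
    count is >= 5, otherwise Fisher's exact test (two-sided). A zero row or
    column margin makes the comparison vacuous: p = 1 with a warning.
    """
    cells = np.array([[a, b], [c, d]], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be nonnegative")
    n = cells.sum()
    if n == 0:
        raise ValueError("table total must be positive")
    rows = cells.sum(axis=1)
    cols = cells.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        warnings.warn(
            "2x2 table has a zero margin; comparison is degenerate (p = 1)",
            DegenerateTableWarning,
            stacklevel=2,
        )
        return PrevalenceTest("degenerate", None, 1.0)
    expected = np.outer(rows, cols) / n
    if np.all(expected >= FISHER_EXPECTED_MIN):
        stat, p, _, _ = sps.chi2_contingency(cells, correction=False)
        return PrevalenceTest("chi2", float(stat), float(p))
    _, p = sps.fisher_exact(cells, alternative="two-sided")
    return PrevalenceTest("fisher", None, float(p))


def dichotomize_bmi(bmi: float) -> str:
    """``normal`` iff BMI <= 25 kg/m^2, else ``overweight``."""
    if bmi is None or (isinstance(bmi, float) and np.isnan(bmi)):
        raise ValueError("BMI is missing; impute before dichotomizing")
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    return "normal" if bmi <= BMI_OVERWEIGHT_THRESHOLD else "overweight"


def _design_matrix(patients: list[PatientRecord], feature_names: list[str]) -> np.ndarray:
    rows = [
        [1.0 if p.sex == Sex.M else 0.0, p.age_at_index]
        + [float(p.features.get(f, 0)) for f in feature_names if f != "overweight"]
        for p in patients
    ]
    return np.asarray(rows, dtype=float)


def impute_bmi(
    patients: list[PatientRecord],
    dictionary: FeatureDictionary,
    m: int = 5,
    k_donors: int = 5,
    seed: int | None = None,
) -> tuple[list[PatientRecord], list[str]]:
    """Complete missing BMI by predictive mean matching.

    Returns new records (observed BMI values untouched) plus the list of
    imputed patient ids. After imputation the ``overweight`` feature of the
    imputed records is refreshed from the completed BMI.
    """
    missing_idx = [i for i, p in enumerate(patients) if p.bmi is None]
    complete_idx = [i for i, p in enumerate(patients) if p.bmi is not None]
    if not missing_idx:
        return list(patients), []
    if not complete_idx:
        raise ValueError("all BMI values are missing; imputation impossible")
    frac = len(missing_idx) / len(patients)
    if frac >= 0.20:
        raise ValueError(
            f"BMI missingness {frac:.1%} >= 20%; single-equation PMM not supported"
        )
    if len(complete_idx) < 50:
        raise ValueError(
            f"need >= 50 complete records for PMM, got {len(complete_idx)}"
        )

    names = dictionary.names
    x_all = _design_matrix(patients, names)
    y_complete = np.array([patients[i].bmi for i in complete_idx], dtype=float)
    x_complete = x_all[complete_idx]
    # ridge-stabilised least squares (constant features otherwise make it singular)
    xc = np.column_stack([np.ones(len(complete_idx)), x_complete])
    beta = np.linalg.solve(
        xc.T @ xc + 1e-8 * np.eye(xc.shape[1]), xc.T @ y_complete
    )
    pred_complete = xc @ beta
    xm = np.column_stack([np.ones(len(missing_idx)), x_all[missing_idx]])
    pred_missing = xm @ beta

    rng = np.random.default_rng(seed)
    k = min(k_donors, len(complete_idx))
    out = list(patients)
    imputed_ids: list[str] = []
    for j, i in enumerate(missing_idx):
        dist = np.abs(pred_complete - pred_missing[j])
        donors = np.argpartition(dist, k - 1)[:k]
        draws = y_complete[rng.choice(donors, size=m, replace=True)]
        value = float(np.median(draws))
        rec = out[i]
        feats = dict(rec.features)
        if "overweight" in dictionary:
            feats["overweight"] = int(value > BMI_OVERWEIGHT_THRESHOLD)
        out[i] = replace(rec, bmi=value, features=feats)
        imputed_ids.append(rec.patient_id)
    logger.info("imputed BMI for %d of %d patients by PMM (m=%d, k=%d)",
                len(imputed_ids), len(patients), m, k)
    return out, imputed_ids


def prevalence_table(
    patients: list[PatientRecord],
    dictionary: FeatureDictionary,
    bracket_upper_ages: list[float | None] | None = None,
) -> pd.DataFrame:
    """Case/control prevalence per feature x sex x age bracket.

    ``bracket_upper_ages`` entries are upper age limits (subjects with
    ``age_at_index`` strictly below are included) or ``None`` for the
    all-ages bracket. Emits raw p-values and a Benjamini-Hochberg adjusted
    column (per sex x bracket family).
    """
    if bracket_upper_ages is None:
        bracket_upper_ages = [None]
    rows = []
    for sex in (Sex.F, Sex.M):
        for upper in bracket_upper_ages:
            in_bracket = [
                p for p in patients
                if p.sex == sex and (upper is None or p.age_at_index < upper)
            ]
            cases = [p for p in in_bracket if p.label == Label.case]
            controls = [p for p in in_bracket if p.label == Label.control]
            if not cases or not controls:
                continue
            family = []
            for feat in dictionary.names:
                a = sum(p.features.get(feat, 0) for p in cases)
                c = sum(p.features.get(feat, 0) for p in controls)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", DegenerateTableWarning)
                    test = compare_prevalence(a, len(cases) - a, c, len(controls) - c)
                family.append(
                    {
                        "feature": feat,
                        "sex": sex.value,
                        "bracket": "all" if upper is None else f"<{upper:g}",
                        "case_count": a,
                        "case_pct": 100.0 * a / len(cases),
                        "control_count": c,
                        "control_pct": 100.0 * c / len(controls),
                        "test_used": test.test_used,
                        "p_value": test.p_value,
                    }
                )
            pvals = np.array([r["p_value"] for r in family])
            for r, q in zip(family, _benjamini_hochberg(pvals)):
                r["p_bh"] = q
            rows.extend(family)
    return pd.DataFrame(rows)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
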