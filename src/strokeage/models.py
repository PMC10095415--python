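"""Age-bracketed case/control classifier grid with feature importances.

Approach 2, stage 1. For every combination of algorithm (logistic
regression GLM, random forest RF, gradient boosting XGB), sex, and
cumulative age bracket (subjects with age at index strictly below the
bracket's upper age), a classifier separating ischemic-stroke cases from
controls is tuned and fitted:

* 80/20 train/test split, assigned deterministically per patient (hash of
  patient id and seed) so that nested brackets share their held-out sets;
* hyperparameters selected by mean cross-validated AUROC over a random
  grid of 5 candidate draws (5-fold cross-validation, 5 repeats by
  default), then refit on the full training portion;
* AUROC and accuracy reported on the held-out 20% only;
* a normalized feature-importance vector (max scaled to 100) extracted
  from the final model — |standardized coefficient| for GLM, mean impurity
  decrease for RF, total split gain for XGB.

The default grid is 3 algorithms x 17 age brackets x 2 sexes = 102
age-limited models, plus the 6 all-ages reference models the importance
trend is compared against. Controls are age-filtered with the same strict
"<" rule as cases (configurable) so bracket comparisons are not confounded
by the control age distribution. Everything is a pure function of (inputs,
config, seed).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint, uniform
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import (
    RandomizedSearchCV,
    RepeatedStratifiedKFold,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .features import FeatureDictionary
from .io import Label, PatientRecord, Sex

logger = logging.getLogger(__name__)

#: Upper ages of the 17 cumulative age brackets, densest across 45-55 where
#: most historical young-stroke cutoffs fall.
DEFAULT_BRACKET_AGES: tuple[float, ...] = (
    40, 45, 46, 47, 48, 49, 50, 51, 52, 53, 54, 55, 60, 65, 70, 75, 80,
)

MIN_CLASS_SIZE = 20


class Algorithm(str, enum.Enum):
    GLM = "GLM"
    RF = "RF"
    XGB = "XGB"


@dataclass(frozen=True)
class BracketSpec:
    """Cumulative age bracket: age_at_index < upper_age, or all ages."""

    upper_age: float | None  # None = "all"

    @property
    def name(self) -> str:
        return "all" if self.upper_age is None else f"<{self.upper_age:g}"

    def contains(self, age: float) -> bool:
        return self.upper_age is None or age < self.upper_age


def default_brackets(include_all: bool = True) -> list[BracketSpec]:
    out = [BracketSpec(float(a)) for a in DEFAULT_BRACKET_AGES]
    if include_all:
        out.append(BracketSpec(None))
    return out


@dataclass(frozen=True)
class CVConfig:
    folds: int = 5
    repeats: int = 5
    grid_size: int = 5
    test_fraction: float = 0.2


@dataclass(frozen=True)
class ModelResult:
    algorithm: Algorithm
    sex: Sex
    bracket: BracketSpec
    auroc: float
    accuracy: float
    n_case: int
    n_control: int
    importance: dict[str, float]
    tuning: dict = field(default_factory=dict)


def make_brackets(
    patients: list[PatientRecord],
    spec: BracketSpec,
    sex: Sex | str,
    filter_controls: bool = True,
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Cases and controls of one sex restricted to the bracket."""
    sex = Sex(sex)
    cases, controls = [], []
    for p in patients:
        if p.sex != sex:
            continue
        if p.label == Label.case:
            if spec.contains(p.age_at_index):
                cases.append(p)
        elif spec.contains(p.age_at_index) or not filter_controls:
            controls.append(p)
    if not cases or not controls:
        raise ValueError(
            f"bracket {spec.name} ({sex.value}): empty class "
            f"(n_case={len(cases)}, n_control={len(controls)})"
        )
    return cases, controls


def _design(patients: list[PatientRecord], names: list[str]) -> np.ndarray:
    return np.array(
        [[float(p.features.get(f, 0)) for f in names] for p in patients], dtype=float
    )


def _holdout_mask(patients: list[PatientRecord], seed: int, fraction: float) -> np.ndarray:
    """Deterministic per-patient test assignment.

    Each patient is mapped to a uniform deviate by hashing (seed, id);
    patients below ``fraction`` form the held-out set. Because membership
    depends only on the patient and the seed — not on which bracket the
    patient appears in — nested brackets share their train/test assignment,
    so importance trends across brackets are paired rather than jittered by
    independent splits.
    """
    import zlib

    out = np.empty(len(patients), dtype=bool)
    for i, p in enumerate(patients):
        h = zlib.crc32(f"{seed}:{p.patient_id}".encode())
        out[i] = (h / 2**32) < fraction
    return out


def _make_search(algorithm: Algorithm, cv: CVConfig, seed: int) -> RandomizedSearchCV:
    """Random hyperparameter search over documented ranges."""
    splitter = RepeatedStratifiedKFold(
        n_splits=cv.folds, n_repeats=cv.repeats, random_state=seed
    )
    if algorithm is Algorithm.GLM:
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000, solver="lbfgs")),
            ]
        )
        params = {"clf__C": loguniform(5e-2, 2e1)}
    elif algorithm is Algorithm.RF:
        est = RandomForestClassifier(
            random_state=seed, n_jobs=1, min_samples_leaf=5, max_samples=0.8
        )
        params = {
            "n_estimators": randint(40, 90),
            "max_depth": randint(3, 9),
            "max_features": uniform(0.2, 0.6),
        }
    elif algorithm is Algorithm.XGB:
        est = XGBClassifier(
            tree_method="hist",
            n_jobs=1,
            eval_metric="logloss",
            random_state=seed,
        )
        params = {
            "learning_rate": loguniform(0.05, 0.3),
            "max_depth": randint(2, 5),
            "n_estimators": randint(40, 120),
            "subsample": uniform(0.6, 0.4),
        }
    else:  # pragma: no cover
        raise ValueError(f"unknown algorithm {algorithm}")
    return RandomizedSearchCV(
        est,
        params,
        n_iter=cv.grid_size,
        scoring="roc_auc",
        cv=splitter,
        random_state=seed,
        n_jobs=1,
        refit=True,
        error_score="raise",
    )


def extract_importance(model, algorithm: Algorithm, feature_names: list[str]) -> dict[str, float]:
    """Nonnegative per-feature importance rescaled so the maximum is 100."""
    if algorithm is Algorithm.GLM:
        raw = np.abs(model.named_steps["clf"].coef_.ravel())
    elif algorithm is Algorithm.RF:
        raw = np.asarray(model.feature_importances_, dtype=float)
    elif algorithm is Algorithm.XGB:
        gain = model.get_booster().get_score(importance_type="total_gain")
        raw = np.array([gain.get(f"f{i}", 0.0) for i in range(len(feature_names))])
    else:  # pragma: no cover
        raise ValueError(f"unknown algorithm {algorithm}")
    if raw.shape[0] != len(feature_names):
        raise ValueError("importance length does not match feature dictionary")
    mx = raw.max()
    if mx <= 0:
        raise ValueError("all raw feature importances are zero")
    scaled = 100.0 * raw / mx
    return {name: float(v) for name, v in zip(feature_names, scaled)}


def train_bracket_model(
    cases: list[PatientRecord],
    controls: list[PatientRecord],
    algorithm: Algorithm | str,
    dictionary: FeatureDictionary,
    cv: CVConfig = CVConfig(),
    seed: int = 0,
    *,
    sex: Sex | None = None,
    bracket: BracketSpec | None = None,
    class_weighted: bool = False,
) -> ModelResult:
    """Tune, fit and evaluate one classifier; extract its importance vector."""
    algorithm = Algorithm(algorithm)
    if not cases or not controls:
        raise ValueError("both cases and controls must be nonempty")
    if len(cases) < MIN_CLASS_SIZE or len(controls) < MIN_CLASS_SIZE:
        raise ValueError(
            f"need >= {MIN_CLASS_SIZE} subjects per class, got "
            f"{len(cases)} cases / {len(controls)} controls"
        )
    names = dictionary.names
    x = np.vstack([_design(cases, names), _design(controls, names)])
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    if np.all(x.std(axis=0) == 0.0):
        raise ValueError("degenerate input: every feature is constant")

    test_mask = _holdout_mask(cases + controls, seed, cv.test_fraction)
    for cls in (0.0, 1.0):
        if not np.any((y == cls) & ~test_mask) or not np.any((y == cls) & test_mask):
            raise ValueError("degenerate train/test split: a class is missing from one portion")
    x_tr, y_tr = x[~test_mask], y[~test_mask]
    x_te, y_te = x[test_mask], y[test_mask]
    search = _make_search(algorithm, cv, seed)
    if class_weighted and algorithm in (Algorithm.GLM, Algorithm.RF):
        search.estimator.set_params(
            **{("clf__class_weight" if algorithm is Algorithm.GLM else "class_weight"): "balanced"}
        )
    elif class_weighted and algorithm is Algorithm.XGB:
        search.estimator.set_params(scale_pos_weight=len(controls) / len(cases))
    search.fit(x_tr, y_tr)
    best = search.best_estimator_

    prob = best.predict_proba(x_te)[:, 1]
    auroc = float(roc_auc_score(y_te, prob))
    accuracy = float(accuracy_score(y_te, prob >= 0.5))
    importance = extract_importance(best, algorithm, names)
    tuning = {
        "grid": [
            {k: (v.item() if hasattr(v, "item") else v) for k, v in p.items()}
            for p in search.cv_results_["params"]
        ],
        "cv_auroc": [float(v) for v in search.cv_results_["mean_test_score"]],
        "selected": {
            k: (v.item() if hasattr(v, "item") else v)
            for k, v in search.best_params_.items()
        },
        "selected_cv_auroc": float(search.best_score_),
    }
    return ModelResult(
        algorithm=algorithm,
        sex=sex if sex is not None else cases[0].sex,
        bracket=bracket if bracket is not None else BracketSpec(None),
        auroc=auroc,
        accuracy=accuracy,
        n_case=len(cases),
        n_control=len(controls),
        importance=importance,
        tuning=tuning,
    )


def run_model_grid(
    patients: list[PatientRecord],
    dictionary: FeatureDictionary,
    algorithms: tuple[Algorithm, ...] = (Algorithm.GLM, Algorithm.RF, Algorithm.XGB),
    brackets: list[BracketSpec] | None = None,
    sexes: tuple[Sex, ...] = (Sex.F, Sex.M),
    cv: CVConfig = CVConfig(),
    seed: int = 0,
    filter_controls: bool = True,
) -> tuple[list[ModelResult], dict[str, str]]:
    """Train the full (algorithm x bracket x sex) grid.

    Returns the fitted results plus a mapping of failed age-limited cells to
    their error messages. A failed all-ages reference model aborts the grid
    (the importance trend cannot be anchored without it).
    """
    if brackets is None:
        brackets = default_brackets(include_all=True)
    results: list[ModelResult] = []
    errors: dict[str, str] = {}
    cells = [
        (alg, sex, spec) for alg in algorithms for sex in sexes for spec in brackets
    ]
    # one seed per (algorithm, sex): every bracket of a trend shares the same
    # hyperparameter draws and fold structure (common random numbers), so the
    # importance trend is not jittered by per-bracket tuning variation
    child_seeds = [
        int(
            np.random.SeedSequence(
                [seed, list(Algorithm).index(Algorithm(alg)), 0 if Sex(sex) is Sex.F else 1]
            ).generate_state(1)[0]
            % (2**31)
        )
        for (alg, sex, _spec) in cells
    ]
    for (alg, sex, spec), cell_seed in zip(cells, child_seeds):
        key = f"{Algorithm(alg).value}/{Sex(sex).value}/{spec.name}"
        try:
            cases, controls = make_brackets(patients, spec, sex, filter_controls)
            res = train_bracket_model(
                cases, controls, alg, dictionary, cv=cv, seed=cell_seed,
                sex=Sex(sex), bracket=spec,
            )
            results.append(res)
        except ValueError as exc:
            if spec.upper_age is None:
                raise RuntimeError(
                    f"all-ages reference model failed for {key}: {exc}"
                ) from exc
            errors[key] = str(exc)
            logger.warning("bracket model %s failed: %s", key, exc)
    logger.info("model grid: %d fitted, %d failed", len(results), len(errors))
    return results, errors


def results_to_frame(results: list[ModelResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "algorithm": r.algorithm.value,
                "sex": r.sex.value,
                "bracket": r.bracket.name,
                "n_case": r.n_case,
                "n_control": r.n_control,
                "auroc": r.auroc,
                "accuracy": r.accuracy,
            }
            for r in results
        ]
    )


def importance_to_frame(results: list[ModelResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for feat, val in r.importance.items():
            rows.append(
                {
                    "algorithm": r.algorithm.value,
                    "sex": r.sex.value,
                    "bracket": r.bracket.name,
                    "feature": feat,
                    "importance": val,
                }
            )
    return pd.DataFrame(rows)


def mean_importance_heatmap(results: list[ModelResult]) -> pd.DataFrame:
    """Across-algorithm mean importance per (sex, bracket, feature) — the
    heatmap table; per-algorithm vectors remain the analytic objects."""
    df = importance_to_frame(results)
    return (
        df.groupby(["sex", "bracket", "feature"], as_index=False)["importance"]
        .mean()
    )
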