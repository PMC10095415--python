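"""Seeded synthetic EHR cohorts with a planted change-point age.

The generator emulates the structure of a case/control ischemic-stroke
cohort so that both estimation approaches can be validated by parameter
recovery:

* ages at index are drawn from Beta-shaped densities over the configured
  range — cases skewed old (stroke incidence rises with age), controls
  near-uniform;
* each binary clinical feature is Bernoulli with

      logit p = logit(baseline) + case * log(odds_multiplier)
                + slope * (age - 50)
                + [young_profile and case and age < tau_sex] * young_shift

  so prevalence follows a logistic age trend, cases are enriched, and the
  *young-profile* features (PFO-like, migraine-like, ...) carry an extra
  log-odds bump for cases below the planted cut-point ``tau`` — the single
  discontinuity both approaches should recover;
* BMI is Gaussian with MCAR missingness; the ``overweight`` feature is its
  dichotomized form (missing BMI leaves it 0 until imputation);
* every active phenotype emits its ICD-like codes (from a generated toy
  code-to-phecode map) as pre-index diagnosis events; extra age-neutral
  "noise" phenotypes enrich the phecode space without carrying signal.

All randomness flows from one master seed through named substreams, so the
output is byte-identical across runs and components can be regenerated in
isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .features import (
    YOUNG_PROFILE_FEATURES,
    FeatureDictionary,
    default_feature_dictionary,
)
from .io import (
    DiagnosisEvent,
    Label,
    PatientRecord,
    PhecodeMapTable,
    Sex,
    Vocabulary,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureModel:
    """Logistic prevalence model for one binary clinical feature."""

    name: str
    baseline: float  # control prevalence at age 50
    case_odds_multiplier: float = 1.0
    age_slope: float = 0.0  # per year, log-odds scale
    young_profile: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline < 1.0:
            raise ValueError(f"{self.name}: baseline prevalence must lie in (0,1)")
        if self.case_odds_multiplier <= 0:
            raise ValueError(f"{self.name}: odds multiplier must be positive")


def default_feature_models() -> tuple[FeatureModel, ...]:
    """Prevalence models for the 22 Bernoulli features of the default
    dictionary (``overweight`` is derived from BMI, not drawn directly).

    Traditional vascular risk factors rise with age, behavioural and
    young-etiology features are flat or gently declining, and cases are
    enriched through the odds multipliers. Slope magnitudes are deliberately
    modest: the generator's purpose is planted-change-point recovery, and
    steep smooth trends would make the age distribution's bulk — not the
    planted discontinuity — the strongest change-point of the similarity
    trend. Qualitative direction, not magnitude, is what these defaults
    reproduce.
    """
    young = set(YOUNG_PROFILE_FEATURES)
    specs = [
        # name, baseline, case multiplier, age slope
        ("hypertension", 0.30, 2.7, 0.014),
        ("dyslipidemia", 0.25, 2.1, 0.010),
        ("diabetes", 0.15, 1.85, 0.008),
        ("atrial_fibrillation", 0.06, 2.1, 0.012),
        ("heart_failure", 0.05, 2.0, 0.012),
        ("myocardial_infarction", 0.04, 1.85, 0.010),
        ("peripheral_artery_disease", 0.04, 1.7, 0.010),
        ("prior_tia", 0.03, 2.4, 0.006),
        ("current_smoking", 0.25, 1.15, -0.002),
        ("alcohol_abuse", 0.08, 1.15, -0.002),
        ("drug_abuse", 0.05, 1.3, -0.006),
        ("mood_disorder", 0.18, 1.15, 0.000),
        ("anxiety_disorder", 0.15, 1.4, -0.002),
        ("neoplasm", 0.05, 1.55, 0.010),
        ("rheumatic_disease", 0.03, 1.15, 0.004),
        ("giant_cell_arteritis", 0.005, 1.0, 0.004),
        ("family_history_stroke_mi", 0.15, 1.55, 0.000),
        ("migraine", 0.20, 1.3, -0.006),
        ("pfo", 0.12, 1.5, -0.004),
        ("hypercoagulable_state", 0.08, 1.5, -0.002),
        ("cervicocephalic_dissection", 0.04, 1.5, -0.002),
        ("fibromuscular_dysplasia", 0.005, 1.4, 0.000),
    ]
    return tuple(
        FeatureModel(name, base, mult, slope, young_profile=name in young)
        for name, base, mult, slope in specs
    )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full description of one synthetic cohort draw."""

    n_cases: int = 2000
    n_controls: int = 8000
    sex_ratio: float = 0.485  # fraction female
    age_min: float = 18.0
    age_max: float = 95.0
    tau_f: float = 53.0
    tau_m: float = 52.0
    young_shift: float = 2.0
    feature_models: tuple[FeatureModel, ...] = field(default_factory=default_feature_models)
    case_age_beta: tuple[float, float] = (1.8, 1.4)
    control_age_beta: tuple[float, float] = (1.1, 1.1)
    n_noise_phenotypes: int = 20
    noise_prevalence_range: tuple[float, float] = (0.02, 0.15)
    codes_per_phenotype: int = 3
    code_emission_prob: float = 0.6
    bmi_mean: float = 28.5
    bmi_sd: float = 6.0
    bmi_missing_frac: float = 0.023
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_cases < 1:
            errors.append("n_cases must be >= 1")
        if self.n_controls < 0:
            errors.append("n_controls must be >= 0")
        if not 0.0 < self.sex_ratio < 1.0:
            errors.append(f"sex_ratio must lie in (0,1), got {self.sex_ratio}")
        if not self.age_min < self.age_max:
            errors.append("age_min must be < age_max")
        if self.age_min < 18.0:
            errors.append("age_min must be >= 18 (adult cohort)")
        for tau, name in ((self.tau_f, "tau_f"), (self.tau_m, "tau_m")):
            if not self.age_min < tau < self.age_max:
                errors.append(f"{name}={tau} must lie inside the age range")
        if not 0.0 <= self.bmi_missing_frac < 1.0:
            errors.append("bmi_missing_frac must lie in [0,1)")
        if self.codes_per_phenotype < 1:
            errors.append("codes_per_phenotype must be >= 1")
        if not 0.0 < self.code_emission_prob <= 1.0:
            errors.append("code_emission_prob must lie in (0,1]")
        lo, hi = self.noise_prevalence_range
        if not 0.0 < lo <= hi < 1.0:
            errors.append("noise_prevalence_range must satisfy 0 < lo <= hi < 1")
        names = [f.name for f in self.feature_models]
        if len(set(names)) != len(names):
            errors.append("duplicate feature model names")
        if errors:
            raise ValueError("invalid cohort config: " + "; ".join(errors))


def null_config(base: SyntheticCohortConfig | None = None, **overrides) -> SyntheticCohortConfig:
    """A no-association configuration for permutation-null experiments.

    Removes the planted change-point (``young_shift = 0``) *and* the smooth
    logistic age trends (all slopes zero), leaving scores exchangeable with
    respect to age — the hypothesis a label-permutation null embodies.
    """
    base = base or SyntheticCohortConfig()
    flat = tuple(replace(fm, age_slope=0.0) for fm in base.feature_models)
    return replace(base, young_shift=0.0, feature_models=flat, **overrides)


def make_toy_phecode_map(
    n_phenotypes: int, codes_per_phenotype: int, seed: int = 0
) -> PhecodeMapTable:
    """Synthetic code-to-phecode map: disjoint code sets, one phecode each.

    Codes look ICD-like (``SYN<phenotype>.<j>``) and alternate between the
    two vocabularies so both lookup paths are exercised.
    """
    if n_phenotypes < 1 or codes_per_phenotype < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_phenotypes):
        phecode = f"P{i + 1:03d}"
        for j in range(codes_per_phenotype):
            vocab = Vocabulary.ICD10CM if rng.random() < 0.5 else Vocabulary.ICD9CM
            rows.append((vocab, f"SYN{i + 1:03d}.{j}", phecode))
    return PhecodeMapTable(rows)


def _scaled_beta(rng: np.random.Generator, ab: tuple[float, float], lo: float,
                 hi: float, size: int) -> np.ndarray:
    return lo + (hi - lo) * rng.beta(ab[0], ab[1], size=size)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(
    config: SyntheticCohortConfig,
    dictionary: FeatureDictionary | None = None,
) -> tuple[list[PatientRecord], list[DiagnosisEvent], PhecodeMapTable]:
    """Draw one cohort: patients, pre-index diagnoses, and the toy map."""
    config.validate()
    dictionary = dictionary or default_feature_dictionary()
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("ages", "sex", "features", "bmi", "missing", "codes", "noise"),
            ss.spawn(7),
        )
    }
    map_seed = int(np.random.SeedSequence([config.seed, 7]).generate_state(1)[0] % (2**31))

    n = config.n_cases + config.n_controls
    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_cases] = True
    is_female = streams["sex"].random(n) < config.sex_ratio

    ages = np.where(
        is_case,
        _scaled_beta(streams["ages"], config.case_age_beta, config.age_min, config.age_max, n),
        _scaled_beta(streams["ages"], config.control_age_beta, config.age_min, config.age_max, n),
    )
    tau = np.where(is_female, config.tau_f, config.tau_m)

    models = [fm for fm in config.feature_models if fm.name in dictionary]
    feature_draws: dict[str, np.ndarray] = {}
    for fm in models:
        logit = (
            np.log(fm.baseline / (1.0 - fm.baseline))
            + is_case * np.log(fm.case_odds_multiplier)
            + fm.age_slope * (ages - 50.0)
        )
        if fm.young_profile:
            logit = logit + config.young_shift * (is_case & (ages < tau))
        feature_draws[fm.name] = (
            streams["features"].random(n) < _sigmoid(logit)
        ).astype(int)

    bmi = streams["bmi"].normal(config.bmi_mean, config.bmi_sd, size=n)
    bmi = np.clip(bmi, 12.0, 70.0)
    bmi_missing = streams["missing"].random(n) < config.bmi_missing_frac
    overweight = (bmi > 25.0).astype(int)
    overweight[bmi_missing] = 0  # unknown BMI -> absence-of-code semantics

    # phenotype space: one phecode per Bernoulli feature, plus noise phenotypes
    code_phenos = [fm.name for fm in models]
    n_pheno = len(code_phenos) + config.n_noise_phenotypes
    table = make_toy_phecode_map(n_pheno, config.codes_per_phenotype, seed=map_seed)
    frame = table.to_frame()
    codes_by_pheno: dict[int, list[tuple[Vocabulary, str]]] = {}
    for row in frame.itertuples(index=False):
        idx = int(row.phecode[1:]) - 1
        codes_by_pheno.setdefault(idx, []).append((Vocabulary(row.vocabulary), row.code))

    lo, hi = config.noise_prevalence_range
    noise_prev = streams["noise"].uniform(lo, hi, size=config.n_noise_phenotypes)
    noise_active = (
        streams["noise"].random((n, config.n_noise_phenotypes)) < noise_prev[None, :]
    )

    patients: list[PatientRecord] = []
    events: list[DiagnosisEvent] = []
    rng_codes = streams["codes"]
    emission = rng_codes.random((n, n_pheno, config.codes_per_phenotype)) < config.code_emission_prob
    fallback = rng_codes.integers(0, config.codes_per_phenotype, size=(n, n_pheno))
    days = rng_codes.integers(0, 3651, size=(n, n_pheno, config.codes_per_phenotype))

    for i in range(n):
        pid = f"S{i + 1:06d}"
        feats = {name: int(feature_draws[name][i]) for name in feature_draws}
        if "overweight" in dictionary:
            feats["overweight"] = int(overweight[i])
        patients.append(
            PatientRecord(
                patient_id=pid,
                sex=Sex.F if is_female[i] else Sex.M,
                age_at_index=float(ages[i]),
                label=Label.case if is_case[i] else Label.control,
                bmi=None if bmi_missing[i] else float(bmi[i]),
                features=feats,
            )
        )
        active = [j for j, name in enumerate(code_phenos) if feature_draws[name][i]]
        active += [len(code_phenos) + j for j in np.nonzero(noise_active[i])[0]]
        for j in active:
            chosen = np.nonzero(emission[i, j])[0]
            if chosen.size == 0:
                chosen = np.array([fallback[i, j]])
            for c in chosen:
                vocab, code = codes_by_pheno[j][int(c)]
                events.append(
                    DiagnosisEvent(
                        patient_id=pid,
                        vocabulary=vocab,
                        code=code,
                        days_before_index=int(days[i, j, int(c)]),
                    )
                )
    logger.info(
        "simulated cohort: %d cases, %d controls, %d diagnosis events, %d phecodes",
        config.n_cases, config.n_controls, len(events), n_pheno,
    )
    return patients, events, table


def mask_bmi_mcar(
    patients: list[PatientRecord], fraction: float, seed: int = 0
) -> list[PatientRecord]:
    """Plant MCAR missingness on BMI (and zero the derived overweight flag)."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0,1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(len(patients)) < fraction
    out = []
    for p, miss in zip(patients, mask):
        if miss and p.bmi is not None:
            feats = dict(p.features)
            if "overweight" in feats:
                feats["overweight"] = 0
            out.append(replace(p, bmi=None, features=feats))
        else:
            out.append(p)
    return out
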