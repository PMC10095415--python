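"""Clinical feature dictionary for the case/control classifiers.

The default dictionary holds the 23 binary clinical variables used to
classify ischemic-stroke cases against stroke-free controls: traditional
vascular risk factors (hypertension, dyslipidemia, diabetes, ...), rarer
etiologies that disproportionately affect younger patients (PFO, migraine,
hypercoagulable states, cervicocephalic dissection, fibromuscular
dysplasia), and behavioural / psychiatric covariates. Each entry carries a
capture-window tag describing when the variable is ascertained relative to
the index encounter: at the index itself, within a three-month buffer after
it (diagnoses that take time to confirm, e.g. hypercoagulable state), or at
any time in the record (lifelong conditions, e.g. fibromuscular dysplasia).
Window tags are metadata only — they configure upstream extraction, not any
computation here — and are therefore freely configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator


VALID_WINDOWS = ("at-index", "three-month-buffer", "any-time")


@dataclass(frozen=True)
class FeatureDef:
    """One binary clinical variable."""

    name: str
    display_name: str
    window: str = "at-index"

    def __post_init__(self) -> None:
        if self.window not in VALID_WINDOWS:
            raise ValueError(
                f"unknown capture window {self.window!r} for feature {self.name!r}; "
                f"expected one of {VALID_WINDOWS}"
            )


@dataclass(frozen=True)
class FeatureDictionary:
    """Ordered collection of clinical features with unique names."""

    features: tuple[FeatureDef, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")

    @classmethod
    def from_defs(cls, defs: Iterable[FeatureDef]) -> "FeatureDictionary":
        return cls(features=tuple(defs))

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[FeatureDef]:
        return iter(self.features)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)


def default_feature_dictionary() -> FeatureDictionary:
    """The default 23-variable clinical dictionary.

    Names are stable identifiers used as CSV column headers; display names
    are for report tables. ``overweight`` is the dichotomized BMI variable
    (BMI > 25 kg/m^2), filled after imputation of the continuous BMI.
    """
    defs = [
        FeatureDef("hypertension", "Hypertension"),
        FeatureDef("dyslipidemia", "Dyslipidemia"),
        FeatureDef("diabetes", "Diabetes mellitus"),
        FeatureDef("atrial_fibrillation", "Atrial fibrillation"),
        FeatureDef("heart_failure", "Heart failure"),
        FeatureDef("myocardial_infarction", "Myocardial infarction"),
        FeatureDef("peripheral_artery_disease", "Peripheral artery disease"),
        FeatureDef("prior_tia", "Prior transient ischemic attack"),
        FeatureDef("overweight", "Overweight (BMI > 25)"),
        FeatureDef("current_smoking", "Current smoking"),
        FeatureDef("alcohol_abuse", "Alcohol abuse or dependence"),
        FeatureDef("drug_abuse", "Drug abuse or dependence"),
        FeatureDef("mood_disorder", "Mood disorder"),
        FeatureDef("anxiety_disorder", "Anxiety disorder"),
        FeatureDef("neoplasm", "Neoplasm"),
        FeatureDef("rheumatic_disease", "Rheumatic disease"),
        FeatureDef("giant_cell_arteritis", "Giant cell arteritis"),
        FeatureDef("family_history_stroke_mi", "Family history of stroke or MI"),
        FeatureDef("migraine", "Migraine"),
        FeatureDef("pfo", "Patent foramen ovale"),
        FeatureDef("hypercoagulable_state", "Hypercoagulable state", "three-month-buffer"),
        FeatureDef("cervicocephalic_dissection", "Cervicocephalic dissection", "three-month-buffer"),
        FeatureDef("fibromuscular_dysplasia", "Fibromuscular dysplasia", "any-time"),
    ]
    return FeatureDictionary.from_defs(defs)


#: Features whose prevalence among cases is concentrated below the young-stroke
#: cut-point; used by the synthetic cohort generator as the planted signal.
YOUNG_PROFILE_FEATURES = (
    "pfo",
    "migraine",
    "hypercoagulable_state",
    "cervicocephalic_dissection",
)
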