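"""Readers, writers, and core domain records for the cohort tables.

Three tabular inputs drive the pipeline:

* ``patients.csv`` — one row per subject: ``patient_id, sex, age_at_index,
  label, bmi, <feature columns>``. ``sex`` is ``F``/``M`` (every analysis is
  sex-stratified), ``label`` is ``case``/``control``, ``bmi`` may be empty.
* ``diagnoses.csv`` — long-format pre-index diagnosis events:
  ``patient_id, vocabulary, code, days_before_index``.
* ``phecode_map.csv`` — many-to-many ``(vocabulary, code) -> phecode``.

All files are comma-separated UTF-8 with a header row and ``.`` decimals.
Validation failures raise :class:`SchemaError` (structural problems) or
:class:`ValidationError` (bad values); row counts and dropped/defaulted rows
are reported through the module logger on standard error.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .features import FeatureDictionary

logger = logging.getLogger(__name__)

MIN_AGE_AT_INDEX = 18.0


class SchemaError(ValueError):
    """A file does not have the expected structure."""


class ValidationError(ValueError):
    """A file parsed but contains invalid values."""


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class Label(str, enum.Enum):
    case = "case"
    control = "control"


class Vocabulary(str, enum.Enum):
    ICD9CM = "ICD9CM"
    ICD10CM = "ICD10CM"


@dataclass
class PatientRecord:
    """One subject: demographics, outcome label, and binary clinical features.

    ``bmi`` is continuous (kg/m^2) and may be ``None`` when missing; the
    ``overweight`` feature is its dichotomized form, filled downstream after
    imputation. ``features`` maps every name of the configured feature
    dictionary to 0/1.
    """

    patient_id: str
    sex: Sex
    age_at_index: float
    label: Label
    bmi: float | None = None
    features: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_at_index < MIN_AGE_AT_INDEX:
            raise ValidationError(
                f"patient {self.patient_id}: age_at_index {self.age_at_index} < {MIN_AGE_AT_INDEX}"
            )


@dataclass(frozen=True)
class DiagnosisEvent:
    """One pre-index diagnosis code occurrence."""

    patient_id: str
    vocabulary: Vocabulary
    code: str
    days_before_index: int


class PhecodeMapTable:
    """Deterministic many-to-many lookup from (vocabulary, code) to phecodes.

    Unmapped codes yield the empty set.
    """

    def __init__(self, rows: Iterable[tuple[Vocabulary, str, str]]):
        table: dict[tuple[Vocabulary, str], set[str]] = {}
        n = 0
        for vocab, code, phecode in rows:
            table.setdefault((Vocabulary(vocab), code), set()).add(str(phecode))
            n += 1
        if n == 0:
            raise SchemaError("phecode map is empty")
        self._table = table

    def lookup(self, vocabulary: Vocabulary | str, code: str) -> set[str]:
        return set(self._table.get((Vocabulary(vocabulary), code), set()))

    @property
    def n_codes(self) -> int:
        return len(self._table)

    @property
    def phecodes(self) -> set[str]:
        out: set[str] = set()
        for s in self._table.values():
            out |= s
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (vocab.value, code, phe)
            for (vocab, code), phes in sorted(
                self._table.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
            )
            for phe in sorted(phes)
        ]
        return pd.DataFrame(rows, columns=["vocabulary", "code", "phecode"])


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_patient_table(path: str | Path, dictionary: FeatureDictionary) -> list[PatientRecord]:
    """Read and validate ``patients.csv`` into :class:`PatientRecord` rows.

    Feature cells may be 0/1 or empty; empty cells default to 0 (EHR
    absence-of-code semantics) and the defaulted count is logged. Missing BMI
    is preserved as ``None``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, ["patient_id", "sex", "age_at_index", "label"], path)

    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate patient_id(s): {sorted(set(dup))[:10]}")

    bad_sex = sorted(set(df["sex"]) - {s.value for s in Sex})
    if bad_sex:
        raise ValidationError(
            f"{path}: sex must be one of F/M (analyses are sex-stratified); got {bad_sex}"
        )
    bad_label = sorted(set(df["label"]) - {l.value for l in Label})
    if bad_label:
        raise ValidationError(f"{path}: label must be case/control; got {bad_label}")

    ages = pd.to_numeric(df["age_at_index"], errors="coerce")
    if ages.isna().any():
        bad = df.loc[ages.isna(), "patient_id"].tolist()
        raise ValidationError(f"{path}: non-numeric age_at_index for ids {bad[:10]}")
    underage = df.loc[ages < MIN_AGE_AT_INDEX, "patient_id"].tolist()
    if underage:
        raise ValidationError(
            f"{path}: age_at_index < {MIN_AGE_AT_INDEX} for ids {underage[:10]}"
        )

    feature_names = dictionary.names
    n_defaulted = 0
    records: list[PatientRecord] = []
    bmi_col = pd.to_numeric(df["bmi"], errors="coerce") if "bmi" in df.columns else None
    for i, row in enumerate(df.itertuples(index=False)):
        feats: dict[str, int] = {}
        for name in feature_names:
            val = getattr(row, name, None) if name in df.columns else None
            if val is None or (isinstance(val, float) and math.isnan(val)):
                feats[name] = 0
                n_defaulted += 1
            else:
                ival = int(val)
                if ival not in (0, 1):
                    raise ValidationError(
                        f"{path}: feature {name!r} for patient {row.patient_id} is {val!r}, expected 0/1"
                    )
                feats[name] = ival
        bmi = None
        if bmi_col is not None and not math.isnan(bmi_col.iloc[i]):
            bmi = float(bmi_col.iloc[i])
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                sex=Sex(row.sex),
                age_at_index=float(ages.iloc[i]),
                label=Label(row.label),
                bmi=bmi,
                features=feats,
            )
        )
    logger.info(
        "read %d patients from %s (%d empty feature cells defaulted to 0)",
        len(records), path, n_defaulted,
    )
    return records


def read_diagnosis_table(path: str | Path) -> list[DiagnosisEvent]:
    """Read ``diagnoses.csv``; drop (and count) post-index events.

    ``days_before_index`` counts days prior to the index encounter; 0 means
    the index day itself and is retained — index-day codes encode presenting
    comorbidities. Negative values denote post-index codes and are excluded.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "code": str})
    _require_columns(df, ["patient_id", "vocabulary", "code", "days_before_index"], path)

    bad_vocab = sorted(set(df["vocabulary"]) - {v.value for v in Vocabulary})
    if bad_vocab:
        raise SchemaError(f"{path}: unknown vocabulary value(s): {bad_vocab}")

    days = pd.to_numeric(df["days_before_index"], errors="coerce")
    if days.isna().any():
        raise SchemaError(f"{path}: non-numeric days_before_index")

    post_index = int((days < 0).sum())
    keep = days >= 0
    events = [
        DiagnosisEvent(
            patient_id=str(r.patient_id),
            vocabulary=Vocabulary(r.vocabulary),
            code=str(r.code),
            days_before_index=int(d),
        )
        for r, d in zip(df[keep].itertuples(index=False), days[keep])
    ]
    logger.info(
        "read %d diagnosis events from %s (%d post-index events dropped)",
        len(events), path, post_index,
    )
    return events


def read_phecode_map(path: str | Path) -> PhecodeMapTable:
    """Read ``phecode_map.csv`` (one row per (code, phecode) pair)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty phecode map file") from None
    _require_columns(df, ["vocabulary", "code", "phecode"], path)
    if df.empty:
        raise SchemaError(f"{path}: empty phecode map file")
    for offset, row in enumerate(df.itertuples(index=False)):
        if any(pd.isna(v) or str(v) == "" for v in (row.vocabulary, row.code, row.phecode)):
            raise SchemaError(f"{path}: malformed row at line {offset + 2}")
        if row.vocabulary not in {v.value for v in Vocabulary}:
            raise SchemaError(
                f"{path}: unknown vocabulary {row.vocabulary!r} at line {offset + 2}"
            )
    table = PhecodeMapTable(
        (Vocabulary(r.vocabulary), str(r.code), str(r.phecode))
        for r in df.itertuples(index=False)
    )
    logger.info("read phecode map from %s: %d codes, %d phecodes", path, table.n_codes, len(table.phecodes))
    return table


# ---------------------------------------------------------------------------
# writers


def patients_to_frame(records: Iterable[PatientRecord], dictionary: FeatureDictionary) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "patient_id": r.patient_id,
            "sex": r.sex.value,
            "age_at_index": r.age_at_index,
            "label": r.label.value,
            "bmi": r.bmi,
        }
        for name in dictionary.names:
            row[name] = r.features.get(name, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_patient_table(records: Iterable[PatientRecord], path: str | Path,
                        dictionary: FeatureDictionary) -> None:
    df = patients_to_frame(records, dictionary)
    df.to_csv(path, index=False)


def write_diagnosis_table(events: Iterable[DiagnosisEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.patient_id, e.vocabulary.value, e.code, e.days_before_index) for e in events],
        columns=["patient_id", "vocabulary", "code", "days_before_index"],
    )
    df.to_csv(path, index=False)


def write_phecode_map(table: PhecodeMapTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)
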