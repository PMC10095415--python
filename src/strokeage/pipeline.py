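"""Stage orchestration shared by the command-line interface and scripts.

Each ``run_*`` function chains the library stages for one analysis, writes
the stage outputs (TSV/JSON) under an output directory, and returns the key
results. A :class:`RunManifest` records the frozen configuration, seed,
input digests, package version, and per-stage row counts and timings, so a
run can be audited and reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .cutpoint import CutpointResult, estimate_cutpoint, loess_smooth
from .features import FeatureDictionary, default_feature_dictionary
from .io import (
    DiagnosisEvent,
    Label,
    PatientRecord,
    PhecodeMapTable,
    Sex,
    write_diagnosis_table,
    write_patient_table,
    write_phecode_map,
)
from .models import CVConfig, default_brackets, results_to_frame, importance_to_frame, run_model_grid
from .similarity import (
    build_phenotype_matrix,
    map_to_phecodes,
    median_similarity_profile,
    profiles_to_frame,
)
from .simulate import SyntheticCohortConfig, simulate_cohort
from .trend import cutpoints_to_dict, estimate_bracket_cutpoint, importance_similarity_trend

logger = logging.getLogger(__name__)


class RunManifest:
    """Auditable record of one pipeline run."""

    def __init__(self, command: str, config: dict[str, Any], seed: int | None):
        self.data: dict[str, Any] = {
            "command": command,
            "package_version": __version__,
            "seed": seed,
            "config": config,
            "inputs": {},
            "stages": [],
            "status": "running",
        }

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        self.data["inputs"][p.name] = {"path": str(p), "sha256": digest}

    def add_stage(self, name: str, n_rows: int, elapsed: float) -> None:
        self.data["stages"].append(
            {"stage": name, "rows": n_rows, "seconds": round(elapsed, 3)}
        )

    def finish(self, out_dir: str | Path, status: str = "ok") -> Path:
        self.data["status"] = status
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, default=str))
        return path


def _timed(manifest: RunManifest, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            self.rows = 0
            return self

        def __exit__(self, *exc):
            if exc[0] is None:
                manifest.add_stage(name, self.rows, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_simulate(
    config: SyntheticCohortConfig,
    out_dir: str | Path,
    dictionary: FeatureDictionary | None = None,
) -> tuple[list[PatientRecord], list[DiagnosisEvent], PhecodeMapTable]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dictionary = dictionary or default_feature_dictionary()
    manifest = RunManifest("simulate", dataclasses.asdict(config), config.seed)
    with _timed(manifest, "simulate_cohort") as t:
        patients, events, table = simulate_cohort(config, dictionary)
        t.rows = len(patients)
    write_patient_table(patients, out / "patients.csv", dictionary)
    write_diagnosis_table(events, out / "diagnoses.csv")
    write_phecode_map(table, out / "phecode_map.csv")
    manifest.finish(out)
    return patients, events, table


def run_approach1(
    patients: list[PatientRecord],
    events: list[DiagnosisEvent],
    table: PhecodeMapTable,
    out_dir: str | Path,
    sexes: tuple[Sex, ...] = (Sex.F, Sex.M),
    epsilon: float = 0.1,
    loess_span: float = 0.75,
    block_size: int = 512,
) -> dict[Sex, CutpointResult]:
    """Phenotype-similarity trend analysis with cut-point estimation.

    Control rows are ignored (with a logged count): the similarity trend is
    defined on the stroke cases' comorbidity profiles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        "approach1",
        {"epsilon": epsilon, "loess_span": loess_span, "block_size": block_size,
         "sexes": [s.value for s in sexes]},
        None,
    )
    n_controls = sum(1 for p in patients if p.label == Label.control)
    if n_controls:
        logger.info("approach 1 ignores %d control rows (cases only)", n_controls)
    if not events:
        raise ValueError("diagnosis table is empty; cannot build phenotype profiles")

    with _timed(manifest, "map_to_phecodes") as t:
        phe_sets = map_to_phecodes(events, table)
        t.rows = len(phe_sets)

    ages = {p.patient_id: p.age_at_index for p in patients}
    cutpoints: dict[Sex, CutpointResult] = {}
    all_profiles = []
    trend_frames = []
    for sex in sexes:
        with _timed(manifest, f"similarity_{sex.value}") as t:
            matrix = build_phenotype_matrix(phe_sets, patients, sex)
            profiles = median_similarity_profile(matrix, ages, block_size=block_size)
            t.rows = len(profiles)
        all_profiles.extend(profiles)
        a = [p.age_at_index for p in profiles]
        s = [p.median_similarity for p in profiles]
        with _timed(manifest, f"cutpoint_{sex.value}") as t:
            cutpoints[sex] = estimate_cutpoint(a, s, epsilon=epsilon)
            t.rows = len(cutpoints[sex].candidates)
        curve = loess_smooth(a, s, span=loess_span)
        trend_frames.append(
            pd.DataFrame({"sex": sex.value, "age": curve.ages, "fitted": curve.fitted})
        )

    profiles_to_frame(all_profiles).to_csv(out / "similarity_profile.tsv", sep="\t", index=False)
    pd.concat(trend_frames).to_csv(out / "trend.tsv", sep="\t", index=False)
    (out / "cutpoint.json").write_text(
        json.dumps({sex.value: res.to_dict() for sex, res in cutpoints.items()}, indent=2)
    )
    manifest.finish(out)
    return cutpoints


def run_approach2(
    patients: list[PatientRecord],
    out_dir: str | Path,
    dictionary: FeatureDictionary | None = None,
    epsilon: float = 0.1,
    cv: CVConfig = CVConfig(),
    seed: int = 0,
    brackets=None,
):
    """Classifier grid, importance-similarity trend, and bracket cut-points."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dictionary = dictionary or default_feature_dictionary()
    manifest = RunManifest(
        "approach2", {"epsilon": epsilon, "cv": dataclasses.asdict(cv)}, seed
    )
    if brackets is None:
        brackets = default_brackets(include_all=True)
    with _timed(manifest, "run_model_grid") as t:
        results, errors = run_model_grid(
            patients, dictionary, brackets=brackets, cv=cv, seed=seed
        )
        t.rows = len(results)
    results_to_frame(results).to_csv(out / "model_grid.tsv", sep="\t", index=False)
    importance_to_frame(results).to_csv(out / "importance.tsv", sep="\t", index=False)
    (out / "tuning.json").write_text(
        json.dumps(
            {
                f"{r.algorithm.value}/{r.sex.value}/{r.bracket.name}": r.tuning
                for r in results
            },
            indent=2,
        )
    )
    with _timed(manifest, "importance_trend") as t:
        trend = importance_similarity_trend(results)
        t.rows = sum(len(v) for v in trend.series.values())
    trend.to_frame().to_csv(out / "importance_trend.tsv", sep="\t", index=False)
    with _timed(manifest, "bracket_cutpoints") as t:
        cutpoints = estimate_bracket_cutpoint(trend, epsilon=epsilon)
        t.rows = len(cutpoints)
    (out / "bracket_cutpoints.json").write_text(
        json.dumps(cutpoints_to_dict(cutpoints), indent=2)
    )
    if errors:
        (out / "bracket_errors.json").write_text(json.dumps(errors, indent=2))
    manifest.finish(out, status="ok" if not errors else "partial")
    return results, trend, cutpoints, errors
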