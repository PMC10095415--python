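"""Cosine-similarity trend of feature importances across age brackets.

Approach 2, stage 2. For each (algorithm, sex), every age-limited bracket's
feature-importance vector is compared against the same algorithm and sex's
all-ages reference vector with cosine similarity. Importances are
nonnegative (max-100 scaled, not re-centered), so each similarity lies in
[0, 1]: a bracket whose classifier relies on the same risk factors as the
all-ages model scores near 1, while a young bracket dominated by a
different risk profile (PFO, migraine, hypercoagulable states, ...) scores
lower. The resulting (bracket upper age, similarity) series is handed to
the maximally selected Wilcoxon engine; its change-point is the estimated
young-stroke age cut-point for that algorithm and sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cutpoint import CutpointResult, estimate_cutpoint
from .io import Sex
from .models import Algorithm, ModelResult
from .similarity import cosine_similarity

logger = logging.getLogger(__name__)

MIN_TREND_POINTS = 4


@dataclass(frozen=True)
class ImportanceTrend:
    """Per (algorithm, sex): bracket upper ages with similarity scores."""

    series: dict[tuple[Algorithm, Sex], list[tuple[float, float]]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "algorithm": alg.value,
                "sex": sex.value,
                "bracket_upper_age": age,
                "similarity": sim,
            }
            for (alg, sex), pairs in sorted(
                self.series.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
            )
            for age, sim in pairs
        ]
        return pd.DataFrame(rows)


def importance_similarity_trend(results: list[ModelResult]) -> ImportanceTrend:
    """Cosine similarity of each bracket's importances to the "all" reference."""
    refs: dict[tuple[Algorithm, Sex], ModelResult] = {}
    limited: list[ModelResult] = []
    for r in results:
        if r.bracket.upper_age is None:
            refs[(r.algorithm, r.sex)] = r
        else:
            limited.append(r)
    series: dict[tuple[Algorithm, Sex], list[tuple[float, float]]] = {}
    for r in limited:
        key = (r.algorithm, r.sex)
        if key not in refs:
            raise ValueError(
                f"missing all-ages reference model for ({key[0].value}, {key[1].value})"
            )
        ref = refs[key]
        names = list(ref.importance)
        sim = cosine_similarity(
            [r.importance[n] for n in names], [ref.importance[n] for n in names]
        )
        series.setdefault(key, []).append((float(r.bracket.upper_age), sim))
    for pairs in series.values():
        pairs.sort(key=lambda t: t[0])
    return ImportanceTrend(series=series)


def estimate_bracket_cutpoint(
    trend: ImportanceTrend, epsilon: float = 0.1
) -> dict[tuple[Algorithm, Sex], CutpointResult]:
    """Change-point of each (algorithm, sex) similarity trend.

    With the 17-bracket default grid, epsilon = 0.1 admits every threshold
    leaving at least 2 brackets on each side.
    """
    out: dict[tuple[Algorithm, Sex], CutpointResult] = {}
    for key, pairs in trend.series.items():
        if len(pairs) < MIN_TREND_POINTS:
            raise ValueError(
                f"trend for ({key[0].value}, {key[1].value}) has only "
                f"{len(pairs)} brackets; need >= {MIN_TREND_POINTS}"
            )
        ages = [a for a, _ in pairs]
        sims = [s for _, s in pairs]
        out[key] = estimate_cutpoint(ages, sims, epsilon=epsilon)
    return out


def cutpoints_to_dict(cutpoints: dict[tuple[Algorithm, Sex], CutpointResult]) -> dict:
    return {
        f"{alg.value}/{sex.value}": res.to_dict()
        for (alg, sex), res in sorted(
            cutpoints.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
        )
    }
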