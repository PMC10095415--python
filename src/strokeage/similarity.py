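"""Patient-similarity profiles on the Phecode comorbidity matrix.

Approach 1 of the pipeline: the pre-index diagnosis codes of ischemic-stroke
cases are mapped to Phecodes, giving a sparse binary patients x phecodes
matrix per sex stratum. For every pair of same-sex patients the cosine
similarity of their phecode membership vectors is computed,

    cos(x, y) = x.y / (|x| |y|)  =  |A n B| / sqrt(|A| |B|)   (binary x, y),

and each patient is summarised by the *median* similarity to all other
patients in the stratum, paired with their age at index stroke. A falling
or stepped median-similarity trend across age marks ages at which the
comorbidity profile of cases changes character; the cut-point engine turns
the trend into a change-point estimate.

Patients with no mapped phecodes have a zero membership vector, where
cosine similarity is undefined; they are excluded from both roles (scored
and comparator) and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .io import DiagnosisEvent, Label, PatientRecord, PhecodeMapTable, Sex

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_SIZE = 512


@dataclass(frozen=True)
class PhenotypeMatrix:
    """Binary patients x phecodes membership matrix for one sex stratum."""

    patient_ids: tuple[str, ...]
    phecodes: tuple[str, ...]
    matrix: sparse.csr_matrix
    sex: Sex

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def zero_rows(self) -> np.ndarray:
        """Indices of patients with no mapped phecodes."""
        counts = np.asarray(self.matrix.sum(axis=1)).ravel()
        return np.nonzero(counts == 0)[0]


@dataclass(frozen=True)
class SimilarityProfile:
    patient_id: str
    sex: Sex
    age_at_index: float
    median_similarity: float
    n_comparisons: int


def map_to_phecodes(
    events: list[DiagnosisEvent], table: PhecodeMapTable
) -> dict[str, set[str]]:
    """Union of phecode lookups per patient; unmapped codes are counted."""
    sets: dict[str, set[str]] = {}
    n_unmapped = 0
    for ev in events:
        phes = table.lookup(ev.vocabulary, ev.code)
        if not phes:
            n_unmapped += 1
        sets.setdefault(ev.patient_id, set()).update(phes)
    logger.info(
        "mapped %d events for %d patients (%d events had no phecode)",
        len(events), len(sets), n_unmapped,
    )
    return sets


def build_phenotype_matrix(
    phecode_sets: dict[str, set[str]],
    patients: list[PatientRecord],
    sex: Sex | str,
) -> PhenotypeMatrix:
    """Assemble the binary matrix for the cases of one sex.

    Rows are the stratum's case patients in input order (patients without
    any diagnosis record get an all-zero row, retained but flagged);
    columns are the sorted union of phecodes observed in the stratum.
    """
    sex = Sex(sex)
    stratum = [p for p in patients if p.sex == sex and p.label == Label.case]
    if not stratum:
        raise ValueError(f"no case patients with sex {sex.value}")
    observed: set[str] = set()
    for p in stratum:
        observed |= phecode_sets.get(p.patient_id, set())
    phecodes = tuple(sorted(observed))
    col = {phe: j for j, phe in enumerate(phecodes)}

    rows, cols = [], []
    for i, p in enumerate(stratum):
        for phe in phecode_sets.get(p.patient_id, ()):  # noqa: B020
            rows.append(i)
            cols.append(col[phe])
    mat = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(stratum), len(phecodes)),
    )
    mat.data[:] = 1  # duplicate (i, j) pairs cannot occur (set input) but keep binary by contract
    pm = PhenotypeMatrix(
        patient_ids=tuple(p.patient_id for p in stratum),
        phecodes=phecodes,
        matrix=mat,
        sex=sex,
    )
    nz = pm.zero_rows()
    if nz.size:
        logger.warning(
            "%d of %d %s cases have no mapped phecodes and will be excluded from similarity",
            nz.size, len(stratum), sex.value,
        )
    return pm


def cosine_similarity(x, y) -> float:
    """Cosine similarity of two nonnegative vectors.

    Undefined (raises) when either vector is all-zero; callers exclude
    zero-phecode patients before scoring.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine similarity is undefined for an all-zero vector")
    # rounding can push the quotient an ulp past 1; clamp to the Cauchy-Schwarz bound
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def median_similarity_profile(
    matrix: PhenotypeMatrix,
    ages: dict[str, float],
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> list[SimilarityProfile]:
    """Median cosine similarity of each patient to all others in the stratum.

    The self-pair is excluded (it would contribute a constant 1 and bias
    every median upward). Zero-phecode patients are excluded from both
    roles. Pairwise scores are computed in row blocks of ``block_size``: for
    binary vectors cos(x, y) = |A n B| / sqrt(|A| |B|), so each block is an
    exact integer intersection-count matmul followed by an elementwise
    division — bit-identical to the naive per-pair computation for any
    block size. Even-sized medians are midpoints of the two central values.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    zero = set(matrix.zero_rows().tolist())
    keep = [i for i in range(matrix.shape[0]) if i not in zero]
    if len(keep) < 2:
        raise ValueError(
            f"need at least 2 patients with nonzero phecode vectors, got {len(keep)}"
        )
    sub = matrix.matrix[keep, :].astype(np.int64)
    sizes = np.asarray(sub.sum(axis=1)).ravel().astype(np.float64)  # |A| per patient
    sub_t = sub.T.tocsc()
    n = sub.shape[0]

    medians = np.empty(n)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        counts = (sub[start:stop, :] @ sub_t).toarray().astype(np.float64)
        sims = counts / np.sqrt(sizes[start:stop, None] * sizes[None, :])
        # drop the self-column of each row before taking the median
        for k in range(stop - start):
            i = start + k
            row = np.delete(sims[k], i)
            medians[i] = np.median(row)

    profiles = [
        SimilarityProfile(
            patient_id=matrix.patient_ids[i],
            sex=matrix.sex,
            age_at_index=float(ages[matrix.patient_ids[i]]),
            median_similarity=float(medians[k]),
            n_comparisons=n - 1,
        )
        for k, i in enumerate(keep)
    ]
    return profiles


def profiles_to_frame(profiles: list[SimilarityProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.patient_id, p.sex.value, p.age_at_index, p.median_similarity, p.n_comparisons)
            for p in profiles
        ],
        columns=["patient_id", "sex", "age_at_index", "median_similarity", "n_comparisons"],
    )
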