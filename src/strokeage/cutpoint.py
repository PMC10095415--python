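"""Maximally selected standardized Wilcoxon cut-point estimation.

Given per-subject pairs ``(age, score)`` — e.g. median phenotype-similarity
versus age at index stroke — the estimator scans every admissible age
threshold ``mu``, splits subjects into {age <= mu} and {age > mu}, and
standardizes the Wilcoxon rank-sum of the left group:

    Z(mu) = |S - E[S]| / sqrt(Var[S])

with ``S`` the left-group rank sum (midranks under ties), ``E[S] =
m(n+1)/2`` and the tie-corrected variance

    Var[S] = m(n-m)/(n(n-1)) * (sum_k r_k^2 - n(n+1)^2/4).

The estimated cut-point is the threshold maximizing ``Z`` — the age at
which the score distribution separates most sharply, i.e. the change-point
of the trend. Admissibility is controlled by the proportion bound
``epsilon``: each side of a candidate split must hold at least a fraction
``epsilon`` of the subjects, which excludes degenerate near-boundary
splits. Because the statistic is rank-based, the estimate is invariant to
any strictly monotone transform of the scores.

A loess smoother (degree-1 local linear regression with tricube weights) is
provided for trend visualisation/reporting only; it never feeds the
estimator, so smoothing choices cannot move the cut-point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 0.1


@dataclass(frozen=True)
class CandidateSplit:
    threshold: float
    statistic: float
    n_left: int
    n_right: int


@dataclass(frozen=True)
class CutpointResult:
    """Estimated change-point with the full candidate scan."""

    cutpoint: float
    max_statistic: float
    epsilon: float
    candidates: tuple[CandidateSplit, ...]
    p_value: float | None = None

    def to_dict(self) -> dict:
        d = {
            "cutpoint": self.cutpoint,
            "max_statistic": self.max_statistic,
            "epsilon": self.epsilon,
            "candidates": [
                {
                    "threshold": c.threshold,
                    "statistic": c.statistic,
                    "n_left": c.n_left,
                    "n_right": c.n_right,
                }
                for c in self.candidates
            ],
        }
        if self.p_value is not None:
            d["p_value"] = self.p_value
        return d


@dataclass(frozen=True)
class TrendCurve:
    ages: np.ndarray
    fitted: np.ndarray
    span: float


class DegenerateTrendWarning(UserWarning):
    """All candidate statistics are zero (scores carry no ordering signal)."""


def standardized_wilcoxon(scores, left_mask) -> float:
    """Standardized two-sample Wilcoxon rank-sum statistic.

    Parameters
    ----------
    scores : array-like of float
        Pooled observations.
    left_mask : array-like of bool
        Membership of the "left" group (size ``m``); the complement forms
        the right group. Both groups must be nonempty.

    Returns
    -------
    float
        ``|S - E[S]| / sqrt(Var[S])`` with midranks under ties; 0.0 when all
        observations are tied (``Var[S] = 0``).
    """
    scores = np.asarray(scores, dtype=float)
    left_mask = np.asarray(left_mask, dtype=bool)
    if scores.shape != left_mask.shape:
        raise ValueError("scores and left_mask must have the same shape")
    n = scores.size
    m = int(left_mask.sum())
    if m == 0 or m == n:
        raise ValueError(f"both groups must be nonempty (m={m}, n={n})")
    r = rankdata(scores)
    s = float(r[left_mask].sum())
    e = m * (n + 1) / 2.0
    var = m * (n - m) / (n * (n - 1.0)) * (float(np.sum(r * r)) - n * (n + 1.0) ** 2 / 4.0)
    if var <= 0.0:
        return 0.0
    return abs(s - e) / np.sqrt(var)


def _scan_statistics(ages: np.ndarray, scores: np.ndarray, epsilon: float):
    """Vectorised candidate scan.

    Returns (thresholds, statistics, n_left) over the admissible distinct
    ages. Equivalent to calling :func:`standardized_wilcoxon` once per
    candidate split — the per-candidate quantities S(m), E(m), Var(m) depend
    on the split only through the left-group size m and the shared midrank
    sum of squares, so a single sort suffices.
    """
    n = ages.size
    order = np.argsort(ages, kind="stable")
    a_sorted = ages[order]
    r = rankdata(scores)[order]

    # split after index i (0-based) => left group = first i+1 subjects;
    # admissible only at boundaries between distinct ages
    boundary = np.nonzero(np.diff(a_sorted) > 0)[0]  # split "after" these indices
    m = boundary + 1
    lo = max(int(np.ceil(epsilon * n)), 1)
    hi = n - lo
    ok = (m >= lo) & (m <= hi)
    m = m[ok]
    boundary = boundary[ok]
    if m.size == 0:
        raise ValueError(
            f"no admissible candidate threshold: n={n}, epsilon={epsilon} "
            f"requires {lo} <= n_left <= {hi} at a distinct-age boundary"
        )
    cum = np.cumsum(r)
    s = cum[boundary]
    e = m * (n + 1) / 2.0
    sum_r2 = float(np.sum(r * r))
    var = m * (n - m) / (n * (n - 1.0)) * (sum_r2 - n * (n + 1.0) ** 2 / 4.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0.0, np.abs(s - e) / np.sqrt(np.maximum(var, 0.0)), 0.0)
    return a_sorted[boundary], z, m


def estimate_cutpoint(
    ages,
    scores,
    epsilon: float = DEFAULT_EPSILON,
    *,
    n_permutations: int = 0,
    seed: int | None = None,
) -> CutpointResult:
    """Estimate the change-point age of a scored age series.

    Candidate thresholds are the distinct observed ages ``mu`` whose split
    {age <= mu} vs {age > mu} leaves each side with at least a fraction
    ``epsilon`` of subjects. The returned cut-point maximizes the
    standardized Wilcoxon statistic; ties break toward the smaller
    threshold. When every candidate statistic is zero (all scores tied) a
    :class:`DegenerateTrendWarning` is emitted and the smallest admissible
    threshold is returned.

    ``n_permutations > 0`` additionally estimates a permutation p-value for
    the maximum statistic by rescanning under random score permutations
    (off by default; the point estimate never depends on it).
    """
    ages = np.asarray(ages, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if ages.shape != scores.shape or ages.ndim != 1:
        raise ValueError("ages and scores must be 1-D arrays of equal length")
    if ages.size < 4:
        raise ValueError(f"need at least 4 (age, score) pairs, got {ages.size}")
    if not np.all(np.isfinite(ages)) or not np.all(np.isfinite(scores)):
        raise ValueError("ages and scores must be finite")
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon must lie in (0, 0.5), got {epsilon}")

    thresholds, z, m = _scan_statistics(ages, scores, epsilon)
    best = int(np.argmax(z))  # argmax returns the first (smallest threshold) among ties
    max_stat = float(z[best])
    if max_stat == 0.0:
        warnings.warn(
            "all candidate statistics are zero; returning the smallest admissible threshold",
            DegenerateTrendWarning,
            stacklevel=2,
        )
    n = ages.size
    candidates = tuple(
        CandidateSplit(float(t), float(stat), int(mi), int(n - mi))
        for t, stat, mi in zip(thresholds, z, m)
    )

    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(scores)
            _, zp, _ = _scan_statistics(ages, perm, epsilon)
            if float(zp.max()) >= max_stat:
                exceed += 1
        p_value = (exceed + 1) / (n_permutations + 1)

    return CutpointResult(
        cutpoint=float(thresholds[best]),
        max_statistic=max_stat,
        epsilon=epsilon,
        candidates=candidates,
        p_value=p_value,
    )


def max_statistic_null_quantile(
    ages,
    scores,
    epsilon: float = DEFAULT_EPSILON,
    *,
    n_permutations: int = 99,
    quantile: float = 0.95,
    seed: int | None = None,
) -> float:
    """Quantile of the permutation null of the maximum statistic.

    Scores are randomly permuted against ages (breaking any age-score
    association while preserving both marginals) and the candidate scan is
    repeated; returns the requested quantile of the resulting maxima.
    """
    ages = np.asarray(ages, dtype=float)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_permutations)
    for i in range(n_permutations):
        _, z, _ = _scan_statistics(ages, rng.permutation(scores), epsilon)
        maxima[i] = z.max()
    return float(np.quantile(maxima, quantile))


def loess_smooth(ages, scores, span: float = 0.75, grid=None) -> TrendCurve:
    """Loess trend of score versus age, for reporting only.

    Degree-1 local linear regression with tricube weights over the
    ``span``-nearest neighbours, evaluated on ``grid`` (default: the sorted
    observed ages). No robustness iterations.
    """
    ages = np.asarray(ages, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if ages.size < 5:
        raise ValueError(f"need at least 5 points for loess, got {ages.size}")
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    k = int(np.ceil(span * ages.size))
    if k < 3:
        raise ValueError(
            f"span {span} yields only {k} neighbours at n={ages.size}; need >= 3"
        )
    if grid is None:
        grid = np.sort(ages)
    grid = np.asarray(grid, dtype=float)
    fitted = lowess(scores, ages, frac=span, it=0, xvals=grid)
    return TrendCurve(ages=grid, fitted=np.asarray(fitted, dtype=float), span=span)
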