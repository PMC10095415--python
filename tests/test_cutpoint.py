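"""Standardized Wilcoxon statistic, maximally selected cut-point, loess."""

import itertools
import math

import numpy as np
import pytest

from strokeage.cutpoint import (
    DegenerateTrendWarning,
    estimate_cutpoint,
    loess_smooth,
    max_statistic_null_quantile,
    standardized_wilcoxon,
)


def _midranks(values):
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def _enumeration_moments(scores, m):
    """Mean and variance of the left-group rank sum over all n! orderings."""
    r = _midranks(scores)
    sums = [sum(perm[:m]) for perm in itertools.permutations(r)]
    mean = sum(sums) / len(sums)
    var = sum((s - mean) ** 2 for s in sums) / len(sums)
    return mean, var


class TestStandardizedWilcoxon:
    def test_reference_value(self):
        # ranks 1..4, left {1,2}: S=3, E=5, Var=5/3
        z = standardized_wilcoxon([1, 2, 3, 4], [True, True, False, False])
        assert z == pytest.approx(2 / math.sqrt(5 / 3), abs=1e-12)
        assert z == pytest.approx(1.549, abs=1e-3)

    def test_all_tied_scores_give_zero(self):
        assert standardized_wilcoxon([5, 5, 5, 5], [True, False, True, False]) == 0.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="nonempty"):
            standardized_wilcoxon([1, 2, 3], [True, True, True])

    @pytest.mark.parametrize(
        "scores",
        [
            [1, 2, 3, 4],
            [1, 1, 2, 2],
            [3, 1, 4, 1, 5],
            [2, 2, 2, 7, 7, 1],
            [1, 5, 5, 5, 2, 2, 9],
        ],
    )
    def test_variance_matches_exhaustive_enumeration(self, scores):
        """Closed-form Var[S] equals the permutation variance, ties included."""
        n = len(scores)
        r = _midranks(scores)
        sum_r2 = sum(x * x for x in r)
        for m in range(1, n):
            mean, var = _enumeration_moments(scores, m)
            closed_var = m * (n - m) / (n * (n - 1)) * (sum_r2 - n * (n + 1) ** 2 / 4)
            assert closed_var == pytest.approx(var, abs=1e-10)
            assert mean == pytest.approx(m * (n + 1) / 2, abs=1e-10)

    def test_tied_split_statistic_matches_label_permutation_sd(self):
        """On [1,1,2,2] the statistic's denominator is the empirical sd of S
        over all 4! orderings of the midranks."""
        scores = [1, 1, 2, 2]
        mask = [True, True, False, False]  # split spans the ties
        mean, var = _enumeration_moments(scores, 2)
        r = _midranks(scores)
        s = r[0] + r[1]
        expected = abs(s - mean) / math.sqrt(var)
        assert standardized_wilcoxon(scores, mask) == pytest.approx(expected, abs=1e-12)


class TestEstimateCutpoint:
    def test_separating_split_wins(self):
        res = estimate_cutpoint([40, 50, 60, 70], [10, 9, 1, 2], epsilon=0.25)
        assert res.cutpoint == 50
        assert res.max_statistic == pytest.approx(2 / math.sqrt(5 / 3), abs=1e-12)
        assert [c.threshold for c in res.candidates] == [40, 50, 60]

    def test_noise_free_step_recovers_boundary(self):
        ages = np.linspace(20, 90, 100)
        scores = np.where(ages <= 53, 1.0, 0.0)
        res = estimate_cutpoint(ages, scores, epsilon=0.1)
        assert res.cutpoint == ages[ages <= 53].max()

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="at least 4"):
            estimate_cutpoint([40, 50, 60], [1, 2, 3], epsilon=0.4)

    def test_no_admissible_candidate_errors(self):
        # only distinct-age boundary leaves 1 vs 3, below the epsilon bound
        with pytest.raises(ValueError, match="epsilon"):
            estimate_cutpoint([40, 70, 70, 70], [1, 2, 3, 4], epsilon=0.3)

    def test_scan_matches_per_candidate_statistic(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(20, 90, 60)
        scores = rng.normal(size=60)
        res = estimate_cutpoint(ages, scores, epsilon=0.1)
        for cand in res.candidates:
            direct = standardized_wilcoxon(scores, ages <= cand.threshold)
            assert cand.statistic == pytest.approx(direct, abs=1e-10)

    @pytest.mark.parametrize("transform", [np.exp, lambda s: 3 * s + 1, np.cbrt])
    def test_invariant_to_monotone_score_transforms(self, transform):
        rng = np.random.default_rng(8)
        ages = rng.uniform(20, 90, 80)
        scores = rng.normal(size=80)
        base = estimate_cutpoint(ages, scores)
        assert estimate_cutpoint(ages, transform(scores)).cutpoint == base.cutpoint

    def test_smaller_epsilon_keeps_the_argmax(self):
        rng = np.random.default_rng(9)
        ages = rng.uniform(20, 90, 50)
        scores = np.where(ages <= 55, 1.0, 0.0) + rng.normal(0, 0.3, 50)
        wide = estimate_cutpoint(ages, scores, epsilon=0.2)
        narrow = estimate_cutpoint(ages, scores, epsilon=0.05)
        assert narrow.cutpoint == wide.cutpoint

    def test_constant_scores_warn_and_return_smallest_threshold(self):
        with pytest.warns(DegenerateTrendWarning):
            res = estimate_cutpoint([40, 50, 60, 70], [1, 1, 1, 1], epsilon=0.25)
        assert res.cutpoint == 40
        assert res.max_statistic == 0.0

    def test_step_recovery_rate_under_noise(self):
        """Planted step with signal-to-noise 2 on a yearly age grid is
        localised to within one grid step in at least 95 of 100 seeded
        replicates."""
        ages = np.repeat(np.arange(20.0, 90.0), 3)  # n = 210, 1-year grid
        step = 53.0
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            scores = np.where(ages <= step, 1.0, 0.0) + rng.normal(0, 0.5, ages.size)
            res = estimate_cutpoint(ages, scores, epsilon=0.1)
            hits += abs(res.cutpoint - step) <= 1.0
        assert hits >= 95

    def test_permutation_p_value_small_for_strong_step(self):
        ages = np.linspace(20, 90, 60)
        scores = np.where(ages <= 50, 1.0, 0.0)
        res = estimate_cutpoint(ages, scores, n_permutations=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_null_quantile_bounds_null_data(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(20, 90, 150)
        scores = rng.normal(size=150)
        q95 = max_statistic_null_quantile(ages, scores, n_permutations=99, seed=1)
        assert q95 > 1.0  # maxima of ~100 candidate statistics exceed 1


class TestLoess:
    def test_reproduces_linear_data(self):
        ages = np.linspace(20, 80, 40)
        curve = loess_smooth(ages, 2 * ages, span=0.5)
        assert np.allclose(curve.fitted, 2 * curve.ages, atol=1e-8)

    def test_constant_data_gives_constant_fit(self):
        ages = np.linspace(20, 80, 30)
        curve = loess_smooth(ages, np.full(30, 3.25), span=0.75)
        assert np.allclose(curve.fitted, 3.25, atol=1e-10)

    def test_denoises_sine_below_noise_level(self):
        rng = np.random.default_rng(12)
        ages = np.sort(rng.uniform(0, 10, 200))
        truth = np.sin(ages)
        scores = truth + rng.normal(0, 0.3, 200)
        curve = loess_smooth(ages, scores, span=0.3, grid=ages)
        rmse = np.sqrt(np.mean((curve.fitted - truth) ** 2))
        assert rmse < 0.3

    def test_span_with_too_few_neighbours_errors(self):
        with pytest.raises(ValueError, match="neighbours"):
            loess_smooth(np.arange(10.0), np.arange(10.0), span=0.2)
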