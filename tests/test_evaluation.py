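"""Rank-sum test, AUC, precision-at-k and the assembled report.

Each statistic is checked against an independent brute-force oracle:
exhaustive label-assignment enumeration for the rank-sum test, pair
counting for AUC, and tie-break permutation averaging for precision-at-k.
"""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from phenorisk.evaluation import (
    auc_mann_whitney,
    default_k_grid,
    evaluate,
    precision_at_k,
    random_baseline_precision,
    wilcoxon_rank_sum,
)
from phenorisk.exceptions import ValidationError


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def auc_pair_counting(cases, controls):
    wins = sum(
        1.0 if c > d else 0.5 if c == d else 0.0
        for c in cases
        for d in controls
    )
    return wins / (len(cases) * len(controls))


def wilcoxon_enumeration(cases, controls):
    """Two-sided exact p by enumerating every case/control label assignment."""
    pooled = np.concatenate([cases, controls])
    n1 = len(cases)
    idx = range(len(pooled))

    def ustat(case_idx):
        case_set = set(case_idx)
        xs = pooled[list(case_idx)]
        ys = pooled[[i for i in idx if i not in case_set]]
        return auc_pair_counting(xs, ys) * n1 * (len(pooled) - n1)

    u_obs = ustat(range(n1))
    us = np.array([ustat(c) for c in itertools.combinations(idx, n1)])
    p = 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean())
    return min(1.0, p)


def precision_tie_permutation_mean(scores, labels, k):
    """Average precision over every ordering of the boundary tie group."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    threshold = np.sort(scores)[::-1][k - 1]
    above = [i for i in range(len(scores)) if scores[i] > threshold]
    tied = [i for i in range(len(scores)) if scores[i] == threshold]
    m = k - len(above)
    vals = [
        (labels[above].sum() + sum(labels[i] for i in perm[:m])) / k
        for perm in itertools.permutations(tied)
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_exact_small_example(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4], mode="exact") == pytest.approx(1 / 3)

    def test_degenerate_identical_values(self):
        assert wilcoxon_rank_sum([5.0], [5.0], mode="normal") == 1.0

    def test_exact_rejects_ties(self):
        with pytest.raises(ValidationError, match="tie"):
            wilcoxon_rank_sum([1, 2], [2, 3], mode="exact")

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 6))
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
            cases, controls = pooled[:n1], pooled[n1:]
            p = wilcoxon_rank_sum(cases, controls, mode="exact")
            assert p == pytest.approx(wilcoxon_enumeration(cases, controls), abs=1e-12)

    def test_auto_switches_to_normal_on_large_or_tied_input(self, rng):
        big = rng.normal(size=200)
        p = wilcoxon_rank_sum(big[:100] + 0.5, big[100:])
        assert 0 < p <= 1


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

class TestAUC:
    def test_tied_pair_example(self):
        assert auc_mann_whitney([3, 1], [0, 1]) == pytest.approx(0.875)

    def test_perfect_separation(self):
        assert auc_mann_whitney([10, 11], [1, 2, 3]) == 1.0

    def test_identical_groups_give_half(self):
        assert auc_mann_whitney([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_matches_pair_counting_and_sklearn(self, rng):
        for _ in range(100):
            n1 = int(rng.integers(1, 100))
            n2 = int(rng.integers(1, 100))
            cases = np.round(rng.normal(0.3, 1, n1), 1)  # rounding induces ties
            controls = np.round(rng.normal(0, 1, n2), 1)
            ours = auc_mann_whitney(cases, controls)
            assert ours == pytest.approx(auc_pair_counting(cases, controls), abs=1e-12)
            labels = np.r_[np.ones(n1), np.zeros(n2)]
            assert ours == pytest.approx(
                roc_auc_score(labels, np.r_[cases, controls]), abs=1e-12
            )


# ---------------------------------------------------------------------------
# precision-at-k
# ---------------------------------------------------------------------------

class TestPrecisionAtK:
    def test_no_tie_example(self):
        assert precision_at_k([5, 4, 3, 2, 1], [1, 0, 1, 0, 0], 2) == 0.5

    def test_k_equals_n_gives_prevalence(self):
        scores = [3, 2, 2, 1]
        labels = [1, 0, 1, 0]
        for policy in ("expected", "pessimistic", "optimistic"):
            assert precision_at_k(scores, labels, 4, policy) == pytest.approx(0.5)

    def test_tie_group_expectation(self):
        assert precision_at_k([3, 2, 2, 2], [1, 1, 0, 0], 2) == pytest.approx(
            (1 + 1 / 3) / 2
        )

    def test_expected_equals_permutation_mean(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 12))
            scores = rng.integers(0, 4, n).astype(float)  # few levels => ties
            # keep boundary tie groups enumerable
            labels = rng.integers(0, 2, n)
            k = int(rng.integers(1, n + 1))
            tied = (scores == np.sort(scores)[::-1][k - 1]).sum()
            if tied > 6:
                continue
            assert precision_at_k(scores, labels, k) == pytest.approx(
                precision_tie_permutation_mean(scores, labels, k), abs=1e-12
            )

    def test_policy_ordering(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            scores = rng.integers(0, 5, n).astype(float)
            labels = rng.integers(0, 2, n)
            k = int(rng.integers(1, n + 1))
            pess = precision_at_k(scores, labels, k, "pessimistic")
            expe = precision_at_k(scores, labels, k, "expected")
            opti = precision_at_k(scores, labels, k, "optimistic")
            assert pess <= expe + 1e-12 <= opti + 2e-12

    def test_k_out_of_range(self):
        with pytest.raises(ValidationError):
            precision_at_k([1, 2], [0, 1], 3)


class TestBaselineAndGrid:
    def test_prevalence_examples(self):
        assert random_baseline_precision([1] * 2 + [0] * 98) == pytest.approx(0.02)
        assert random_baseline_precision([1, 1, 1]) == 1.0

    def test_grid_n50(self):
        assert default_k_grid(50) == [10, 20, 30, 40, 50]

    def test_grid_n1000_has_no_log_tail(self):
        assert default_k_grid(1000) == list(range(10, 101, 10)) + list(range(200, 1001, 100))

    def test_grid_n30000(self):
        grid = default_k_grid(30_000)
        expected_tail = []
        j = 1
        while True:
            v = round(10 ** (3 + j / 3))
            if v >= 30_000:
                break
            expected_tail.append(v)
            j += 1
        assert grid[-1] == 30_000
        assert grid[-len(expected_tail) - 1 : -1] == expected_tail
        assert all(b > a for a, b in zip(grid, grid[1:]))
        assert all(b < 10 * a for a, b in zip(grid, grid[1:]))

    def test_grid_too_small_cohort(self):
        with pytest.raises(ValidationError):
            default_k_grid(9)


# ---------------------------------------------------------------------------
# assembled report
# ---------------------------------------------------------------------------

class TestEvaluate:
    def test_final_curve_point_is_prevalence(self, rng):
        n = 40
        scores = rng.normal(size=n)
        labels = (rng.random(n) < 0.3).astype(int)
        labels[0] = 1
        labels[1] = 0
        report = evaluate(scores, labels)
        k, prec = report.precision_curve[-1]
        assert k == n
        assert prec == pytest.approx(report.baseline_prevalence)

    def test_single_top_case_at_k10(self):
        scores = [10.0] + list(np.linspace(0, 1, 19))
        labels = [1] + [0] * 19
        report = evaluate(scores, labels, k_grid=[10, 20])
        assert report.precision_at(10) == pytest.approx(0.1)

    def test_report_matches_componentwise_recomputation(self, rng):
        scores = np.round(rng.normal(size=20), 1)
        labels = np.array([1] * 6 + [0] * 14)
        report = evaluate(scores, labels, k_grid=[5, 10, 20])
        cases, controls = scores[labels == 1], scores[labels == 0]
        assert report.p_value == pytest.approx(wilcoxon_rank_sum(cases, controls))
        assert report.auc == pytest.approx(auc_mann_whitney(cases, controls))
        for k, prec in report.precision_curve:
            assert prec == pytest.approx(precision_at_k(scores, labels, k))
        assert report.n_cases == 6 and report.n_controls == 14

    def test_requires_both_classes(self):
        with pytest.raises(ValidationError):
            evaluate(np.arange(12.0), np.ones(12, dtype=int))

    def test_bad_grid_rejected(self, rng):
        scores = rng.normal(size=15)
        labels = np.array([1] * 5 + [0] * 10)
        with pytest.raises(ValidationError):
            evaluate(scores, labels, k_grid=[5, 5, 10])
        with pytest.raises(ValidationError):
            evaluate(scores, labels, k_grid=[5, 30])

    def test_json_and_csv_export(self, tmp_path, rng):
        scores = rng.normal(size=30)
        labels = np.array([1] * 8 + [0] * 22)
        report = evaluate(scores, labels, k_grid=[10, 30])
        report.to_json(tmp_path / "r.json")
        report.curve_to_csv(tmp_path / "c.csv")
        import json

        doc = json.loads((tmp_path / "r.json").read_text())
        assert doc["n_cases"] == 8
        lines = (tmp_path / "c.csv").read_text().strip().splitlines()
        assert lines[0] == "k,precision,baseline"
        assert len(lines) == 3
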