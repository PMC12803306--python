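"""Discrimination and prioritization metrics for case-finding scores.

Three complementary views of performance:

* **Wilcoxon rank-sum** — do case and control score distributions differ?
  This is the traditional significance check, but on heavily imbalanced
  cohorts it can be significant even when the distributions overlap almost
  entirely.
* **AUC (Mann-Whitney)** — probability that a random case outscores a
  random control, ties counted one half. Robust to imbalance, but weighs
  the uninteresting low-score end as much as the top.
* **Precision-at-k** — fraction of true cases among the k highest-scoring
  individuals. This models the actual deployment: send the top k for
  confirmatory genetic testing and ask what fraction are carriers. Its
  floor is the cohort prevalence (the expected yield of testing k people
  at random), and at k = n it equals that prevalence exactly.

Ties at the k-boundary are resolved deterministically. With A the set of
individuals scoring strictly above the k-th order statistic and T the tie
group at that score, m = k - |A| boundary slots are filled from T:

* ``expected`` (default) — each tie-group member fills a slot with equal
  probability, so precision = (cases(A) + m * cases(T)/|T|) / k. This is
  the mean over all tie-break orders and needs no random seed.
* ``pessimistic`` — controls from T fill the slots first (lower bound).
* ``optimistic`` — cases from T fill the slots first (upper bound).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError

TIE_POLICIES = ("expected", "pessimistic", "optimistic")


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name} is empty")
    return arr


# ---------------------------------------------------------------------------
# rank-based two-sample statistics
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(case_scores, control_scores, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``mode='auto'`` uses the exact null distribution when the pooled sample
    has at most 12 observations and no ties, and otherwise the tie-corrected
    normal approximation with continuity correction. ``'exact'`` and
    ``'normal'`` force the respective method (exact errors on ties).
    """
    x = _as_1d(case_scores, "case_scores")
    y = _as_1d(control_scores, "control_scores")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if mode == "auto":
        method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    elif mode == "exact":
        if has_ties:
            raise ValidationError("exact Wilcoxon requires tie-free data")
        method = "exact"
    elif mode == "normal":
        method = "asymptotic"
    else:
        raise ValidationError(f"mode must be auto/exact/normal, got {mode!r}")

    if np.unique(pooled).size == 1:
        # zero-variance degenerate case: no separation whatsoever
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def auc_mann_whitney(case_scores, control_scores) -> float:
    """AUC via the rank formula: P(case > control) + 0.5 P(case = control).

    Equivalent to exhaustive pair counting with ties worth one half.
    """
    x = _as_1d(case_scores, "case_scores")
    y = _as_1d(control_scores, "control_scores")
    n1, n2 = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


# ---------------------------------------------------------------------------
# precision-at-k
# ---------------------------------------------------------------------------

def precision_at_k(scores, labels, k: int, tie_policy: str = "expected") -> float:
    """Precision among the k top-scoring individuals, ties handled per policy."""
    s = _as_1d(scores, "scores")
    lab = np.asarray(labels).ravel()
    if lab.size != s.size:
        raise ValidationError("scores and labels must be the same length")
    if not np.isin(lab, [0, 1]).all():
        raise ValidationError("labels must be binary 0/1")
    if not (1 <= k <= s.size):
        raise ValidationError(f"k must be in [1, {s.size}], got {k}")
    if tie_policy not in TIE_POLICIES:
        raise ValidationError(f"tie_policy must be one of {TIE_POLICIES}")

    order = np.sort(s)[::-1]
    threshold = order[k - 1]  # k-th order statistic (descending)
    above = s > threshold
    tied = s == threshold
    cases_above = int(lab[above].sum())
    n_tied = int(tied.sum())
    cases_tied = int(lab[tied].sum())
    m = k - int(above.sum())  # boundary slots filled from the tie group

    if tie_policy == "expected":
        filled = m * cases_tied / n_tied
    elif tie_policy == "optimistic":
        filled = min(m, cases_tied)
    else:  # pessimistic: controls from the tie group enter first
        filled = max(0, m - (n_tied - cases_tied))
    return (cases_above + filled) / k


def random_baseline_precision(labels) -> float:
    """Expected precision of random prioritization at any k: the prevalence."""
    lab = np.asarray(labels).ravel()
    if lab.size == 0:
        raise ValidationError("labels is empty")
    return float(lab.mean())


def default_k_grid(n: int) -> list[int]:
    """The k grid used for precision-at-k curves.

    10 to 100 in steps of 10, 200 to 1000 in steps of 100, then three
    points per decade (10^(1/3) spacing) beyond 1000, always ending at n.
    """
    if n < 10:
        raise ValidationError("k grid needs a cohort of at least 10")
    ks = [k for k in range(10, 101, 10) if k <= n]
    ks += [k for k in range(200, 1001, 100) if k <= n]
    j = 1
    while True:
        v = round(10 ** (3 + j / 3.0))
        if v >= n:
            break
        ks.append(v)
        j += 1
    ks.append(n)
    return sorted(set(ks))


# ---------------------------------------------------------------------------
# assembled report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """All metrics for one scored cohort."""

    p_value: float
    auc: float
    precision_curve: list[tuple[int, float]]
    baseline_prevalence: float
    n_cases: int
    n_controls: int

    def precision_at(self, k: int) -> float:
        for kk, prec in self.precision_curve:
            if kk == k:
                return prec
        raise KeyError(f"k={k} not in the precision curve")

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "auc": self.auc,
            "precision_curve": [{"k": k, "precision": p} for k, p in self.precision_curve],
            "baseline_prevalence": self.baseline_prevalence,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def curve_to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["k", "precision", "baseline"])
            for k, p in self.precision_curve:
                writer.writerow([k, repr(p), repr(self.baseline_prevalence)])


def evaluate(scores, labels, k_grid=None, tie_policy: str = "expected") -> EvalReport:
    """Assemble rank-sum p-value, AUC and a precision-at-k curve.

    ``k_grid`` defaults to :func:`default_k_grid` (requires n >= 10);
    supplied grids must be strictly increasing within [1, n].
    """
    s = _as_1d(scores, "scores")
    lab = np.asarray(labels).ravel()
    if lab.size != s.size:
        raise ValidationError("scores and labels must be the same length")
    n = s.size
    n_cases = int(lab.sum())
    n_controls = n - n_cases
    if n_cases == 0 or n_controls == 0:
        raise ValidationError("need at least one case and one control to evaluate")

    if k_grid is None:
        k_grid = default_k_grid(n)
    else:
        k_grid = [int(k) for k in k_grid]
        if any(b <= a for a, b in zip(k_grid, k_grid[1:])):
            raise ValidationError("k grid must be strictly increasing")
        if k_grid[0] < 1 or k_grid[-1] > n:
            raise ValidationError(f"k grid must lie within [1, {n}]")

    case_scores = s[lab == 1]
    control_scores = s[lab == 0]
    curve = [(k, precision_at_k(s, lab, k, tie_policy)) for k in k_grid]
    return EvalReport(
        p_value=wilcoxon_rank_sum(case_scores, control_scores),
        auc=auc_mann_whitney(case_scores, control_scores),
        precision_curve=curve,
        baseline_prevalence=random_baseline_precision(lab),
        n_cases=n_cases,
        n_controls=n_controls,
    )
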