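"""The treatment-comparison test battery.

Thin, uniformly-shaped wrappers around the scipy tests the analysis uses,
plus the label-permutation test on the coefficient of variation, all
returning :class:`TestResult`.  Everything stochastic is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["TestResult", "compare_groups", "cv"]


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    tails: int = 2
    n_per_group: tuple[int, ...] = ()
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def cv(values) -> float:
    """Coefficient of variation (sample SD over mean)."""
    values = np.asarray(values, dtype=float)
    return float(values.std(ddof=1) / values.mean())


def _perm_cv(a, b, n_perm: int, seed: int) -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    observed = abs(cv(a) - cv(b))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(cv(perm[: a.size]) - cv(perm[a.size :])) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return TestResult(
        "bootstrap_cv", observed, p, 2, (a.size, b.size),
        {"n_perm": n_perm, "seed": seed},
    )


def compare_groups(
    a=None,
    b=None,
    method: str = "welch_t",
    table=None,
    observed=None,
    expected_weights=None,
    k: int | None = None,
    n: int | None = None,
    p_null: float | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Run one named two-group (or goodness-of-fit) test.

    Methods and their inputs:

    - ``welch_t``, ``wilcoxon_rank_sum``, ``levene``, ``bootstrap_cv``:
      per-line value vectors ``a`` and ``b``.
    - ``fisher_exact``, ``chi_square_contingency``: a 2D count ``table``.
    - ``chi_square_gof``: ``observed`` counts and ``expected_weights``
      (normalized internally; e.g. per-arm callable sites, or raw contig
      lengths).
    - ``binomial``: successes ``k`` out of ``n`` against ``p_null``.

    All tests are two-sided.  ``bootstrap_cv`` permutes group labels and
    reports the fraction of permuted |CV difference| at least as large as
    observed (add-one corrected).
    """
    if method in ("welch_t", "wilcoxon_rank_sum", "levene", "bootstrap_cv"):
        if a is None or b is None:
            raise ValueError(f"{method} needs per-group value vectors")
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if method in ("levene", "bootstrap_cv") and min(a.size, b.size) < 2:
            raise ValueError(f"{method} needs n >= 2 per group")
        if method == "welch_t":
            res = stats.ttest_ind(a, b, equal_var=False)
            return TestResult("welch_t", float(res.statistic), float(res.pvalue), 2, (a.size, b.size))
        if method == "wilcoxon_rank_sum":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            return TestResult("wilcoxon_rank_sum", float(res.statistic), float(res.pvalue), 2, (a.size, b.size))
        if method == "levene":
            res = stats.levene(a, b)  # Brown–Forsythe (median-centred)
            return TestResult("levene", float(res.statistic), float(res.pvalue), 2, (a.size, b.size), {"center": "median"})
        return _perm_cv(a, b, n_perm, seed)

    if method == "fisher_exact":
        if table is None:
            raise ValueError("fisher_exact needs a 2x2 table")
        stat, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
        return TestResult("fisher_exact", float(stat), float(p), 2)

    if method == "chi_square_contingency":
        if table is None:
            raise ValueError("chi_square_contingency needs a table")
        res = stats.chi2_contingency(np.asarray(table), correction=False)
        return TestResult(
            "chi_square_contingency", float(res.statistic), float(res.pvalue), 2,
            options={"dof": int(res.dof)},
        )

    if method == "chi_square_gof":
        if observed is None or expected_weights is None:
            raise ValueError("chi_square_gof needs observed and expected_weights")
        observed = np.asarray(observed, dtype=float)
        weights = np.asarray(expected_weights, dtype=float)
        expected = weights / weights.sum() * observed.sum()
        res = stats.chisquare(observed, f_exp=expected)
        return TestResult(
            "chi_square_gof", float(res.statistic), float(res.pvalue), 2,
            options={"dof": observed.size - 1},
        )

    if method == "binomial":
        if k is None or n is None or p_null is None:
            raise ValueError("binomial needs k, n and p_null")
        res = stats.binomtest(k, n, p_null, alternative="two-sided")
        return TestResult(
            "binomial", float(k), float(res.pvalue), 2, (n,), {"p_null": p_null}
        )

    raise ValueError(f"unknown method {method!r}")
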