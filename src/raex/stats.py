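"""Exact and approximate nonparametric tests used across the pipeline.

The exact branches enumerate the full permutation null (all sign
assignments for the signed-rank test, all group labelings for the
rank-sum test) so they remain valid in the presence of tied values,
where closed-form exact distributions do not apply.  Two-sided p-values
use the symmetric-tail convention P(|T - E[T]| >= |t_obs - E[T]|); both
null distributions are symmetric about their mean (rank reflection
r -> N + 1 - r is a bijection even with average-tied ranks), so this
coincides with doubling the smaller tail.

Larger samples fall back to the normal approximation with continuity
and tie corrections via scipy.  Fisher's exact test is scipy's
two-sided convention (sum of tables whose point probability does not
exceed the observed table's), which is the convention assumed here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

_EPS = 1e-12

#: Largest n for which the signed-rank test enumerates all 2**n sign vectors.
SIGNED_RANK_EXACT_LIMIT = 12
#: Largest pooled n+m for which the rank-sum test enumerates all C(n+m, n) labelings.
RANK_SUM_EXACT_LIMIT = 16


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"
    n: int


def _average_ranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _symmetric_tail_p(dist: np.ndarray, observed: float) -> float:
    mu = dist.mean()
    dev = abs(observed - mu)
    return float(np.mean(np.abs(dist - mu) >= dev - _EPS))


def signed_rank_test(diffs, exact_limit: int = SIGNED_RANK_EXACT_LIMIT) -> TestResult:
    """Wilcoxon signed-rank test on paired differences, two-sided.

    Zero differences are dropped (Wilcoxon's convention).  With no
    nonzero differences the null cannot be rejected: statistic 0, p 1.
    Exact enumeration for n <= exact_limit, otherwise the normal
    approximation with continuity and tie corrections.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "exact", 0)
    ranks = _average_ranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        dist = signs @ ranks
        return TestResult(w_plus, _symmetric_tail_p(dist, w_plus), "exact", n)
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return TestResult(w_plus, float(res.pvalue), "normal_approx", n)


def rank_sum_test(x, y, exact_limit: int = RANK_SUM_EXACT_LIMIT) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Statistic is the rank sum of the first group in the pooled ranking.
    Exact enumeration when n + m <= exact_limit, otherwise normal
    approximation with continuity and tie corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires two non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = _average_ranks(pooled)
    w = float(ranks[: x.size].sum())
    n_total = pooled.size
    if n_total <= exact_limit:
        dist = np.array(
            [ranks[list(idx)].sum() for idx in itertools.combinations(range(n_total), x.size)]
        )
        return TestResult(w, _symmetric_tail_p(dist, w), "exact", n_total)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", use_continuity=True, method="asymptotic")
    return TestResult(w, float(res.pvalue), "normal_approx", n_total)


@dataclass(frozen=True)
class OverlapTestResult:
    """Exact test of gene-set overlap against a hypergeometric null."""

    table: tuple[tuple[int, int], tuple[int, int]]
    overlap: int
    expected: float
    fold_enrichment: float
    p_value: float


def hypergeom_overlap_test(n_a: int, n_b: int, overlap: int, background: int) -> OverlapTestResult:
    """Two-tailed Fisher's exact test for the overlap of two gene sets.

    ``expected`` is |A|*|B|/N; fold enrichment is observed/expected
    (inf when expected is 0).
    """
    if background <= 0:
        raise ValueError("background gene set must be non-empty")
    if not (0 <= overlap <= min(n_a, n_b)) or max(n_a, n_b) > background:
        raise ValueError("sets must be subsets of the background")
    table = (
        (overlap, n_a - overlap),
        (n_b - overlap, background - n_a - n_b + overlap),
    )
    if table[1][1] < 0:
        raise ValueError("overlap inconsistent with set and background sizes")
    expected = n_a * n_b / background
    fold = overlap / expected if expected > 0 else math.inf
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return OverlapTestResult(table, overlap, expected, fold, p)
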