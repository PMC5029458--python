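"""Brute-force enumeration oracles, independent of the implementation.

Each oracle recomputes an exact null distribution from first
principles (all sign assignments, all group labelings, all
hypergeometric tables) and derives the two-sided p-value directly
from counting, so the package's exact test routines can be checked
against an implementation-independent reference at small n.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def average_ranks(values):
    """Plain O(n^2) average ranks (1-based), written independently."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2)
    return ranks


def signed_rank_enum(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = average_ranks([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    mu = sum(ranks) / 2
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return w_obs, count / total


def rank_sum_enum(x, y):
    """Exact two-sided rank-sum p by enumerating all C(n+m, n) labelings."""
    pooled = list(x) + list(y)
    ranks = average_ranks(pooled)
    n = len(x)
    w_obs = sum(ranks[:n])
    mu = n * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        w = sum(ranks[i] for i in idx)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return w_obs, count / total


def fisher_enum(n_a, n_b, overlap, background):
    """Two-tailed Fisher p by summing hypergeometric point probabilities.

    Includes every achievable table whose point probability does not
    exceed the observed table's (with a tiny tolerance for float
    round-off).
    """
    def pmf(k):
        return (
            math.comb(n_a, k)
            * math.comb(background - n_a, n_b - k)
            / math.comb(background, n_b)
        )

    lo = max(0, n_a + n_b - background)
    hi = min(n_a, n_b)
    p_obs = pmf(overlap)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-12))


def quantile_normalize_small(columns):
    """Rank-and-average oracle for equal-length complete columns."""
    columns = [list(c) for c in columns]
    sorted_cols = [sorted(c) for c in columns]
    reference = [float(np.mean(vals)) for vals in zip(*sorted_cols)]
    out = []
    for col in columns:
        ranks = average_ranks(col)
        out.append([
            float(np.interp(r, list(range(1, len(col) + 1)), reference)) for r in ranks
        ])
    return out
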