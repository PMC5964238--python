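"""Exact and asymptotic two-sample statistics used by the population analyses.

Fisher's exact test compares responder counts between conditions; the
Mann-Whitney U test compares per-cell measures (maximum 340:380 ratio,
pre/post motility ratios) between groups. Both are two-sided, matching the
way beeswarm/bar-graph comparisons are usually reported for this assay.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["fishers_exact", "mann_whitney"]


def fishers_exact(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 contingency table.

    Uses the minimum-likelihood definition: the p-value is the sum of
    hypergeometric probabilities of all tables (with the observed margins)
    whose probability does not exceed that of the observed table.

    Parameters
    ----------
    table : array-like, shape (2, 2)
        Non-negative integer counts.

    Returns
    -------
    float
        Two-sided p-value.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.all(np.equal(np.mod(t, 1), 0)):
        raise ValueError("table entries must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has an all-zero margin")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(p)


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(group_a, group_b, exact_max_n: int = 8):
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The U statistic is computed from midranks. The p-value is exact
    (permutation enumeration over all group assignments of the pooled
    sample, which handles ties correctly) when both groups have at most
    ``exact_max_n`` observations, and a tie-corrected normal approximation
    with continuity correction otherwise.

    Returns
    -------
    (U, p) : tuple of float
        U is the statistic of ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u = _u_statistic(ranks[:n_a], n_a)

    if n_a <= exact_max_n and n_b <= exact_max_n:
        # Enumerate every assignment of n_a of the pooled midranks to group A.
        n = n_a + n_b
        count = 0
        total = 0
        nm = n_a * n_b
        lo = min(u, nm - u)
        hi = max(u, nm - u)
        eps = 1e-9
        for idx in combinations(range(n), n_a):
            u_perm = _u_statistic(ranks[list(idx)], n_a)
            if u_perm <= lo + eps or u_perm >= hi - eps:
                count += 1
            total += 1
        p = count / total
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return float(u), float(min(p, 1.0))
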