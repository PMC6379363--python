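"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the rank-sum p-value
is obtained by exhaustive enumeration of group assignments, and the AUC by
looping over all case/control pairs.
"""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p by exhaustive enumeration.

    Enumerates every C(n+m, n) assignment of the pooled observations to the
    first group, computes the Mann-Whitney U of each, and returns
    min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))).
    """
    x = list(x)
    y = list(y)
    pooled = np.array(x + y, dtype=float)
    n = len(x)

    def u_stat(idx):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        # count pairs a > b plus half ties
        u = 0.0
        for va in a:
            for vb in b:
                u += (va > vb) + 0.5 * (va == vb)
        return u

    u_obs = u_stat(range(n))
    us = [u_stat(idx) for idx in combinations(range(len(pooled)), n)]
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lo, hi))


def pairwise_auc(case_scores, control_scores) -> float:
    """AUC as the fraction of concordant case/control pairs, ties half."""
    wins = 0.0
    case_scores = list(case_scores)
    control_scores = list(control_scores)
    for c in case_scores:
        for k in control_scores:
            if c > k:
                wins += 1.0
            elif c == k:
                wins += 0.5
    return wins / (len(case_scores) * len(control_scores))


def bh_stepup(p):
    """Reference BH implementation following the textbook definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj
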