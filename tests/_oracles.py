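"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive quantities by enumeration rather than calling
the implementation paths they check.
"""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def exact_ranksum_p_by_enumeration(x, y) -> float:
    """Two-sided exact rank-sum P by enumerating all C(n, n1) assignments."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    c_lo = c_hi = total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if w <= w_obs:
            c_lo += 1
        if w >= w_obs:
            c_hi += 1
    return min(1.0, 2 * min(c_lo, c_hi) / total)


def auc_by_pair_counting(pos, neg) -> float:
    """AUC by direct enumeration of all (pos, neg) pairs, ties half credit."""
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
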