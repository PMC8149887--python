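"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: the rank-sum
null is built by enumerating every assignment of ranks to the first
sample, and the Fisher p by enumerating every 2x2 table with the observed
margins.
"""

from itertools import combinations
from math import comb

import numpy as np
from scipy.special import gammaln


def exact_wilcoxon_two_sided(x, y) -> float:
    """Two-sided rank-sum p by exhaustive enumeration (no ties assumed):
    p = min(1, 2 * min(P(W <= w_obs), P(W >= w_obs)))."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n_x, n = len(x), len(x) + len(y)
    ranks = np.argsort(np.argsort(np.concatenate([x, y]))) + 1
    w_obs = ranks[:n_x].sum()
    all_w = [sum(c) for c in combinations(range(1, n + 1), n_x)]
    total = comb(n, n_x)
    lower = sum(1 for w in all_w if w <= w_obs) / total
    upper = sum(1 for w in all_w if w >= w_obs) / total
    return min(1.0, 2.0 * min(lower, upper))


def _log_table_prob(a, b, c, d):
    """Hypergeometric probability of a 2x2 table with fixed margins."""
    n = a + b + c + d
    num = (gammaln(a + b + 1) + gammaln(c + d + 1)
           + gammaln(a + c + 1) + gammaln(b + d + 1))
    den = (gammaln(n + 1) + gammaln(a + 1) + gammaln(b + 1)
           + gammaln(c + 1) + gammaln(d + 1))
    return num - den


def exact_fisher(a, b, c, d, sidedness="greater") -> float:
    """Fisher p by enumerating all tables with the observed margins."""
    row1, col1 = a + b, a + c
    n = a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    obs = np.exp(_log_table_prob(a, b, c, d))
    p = 0.0
    for aa in range(lo, hi + 1):
        bb, cc = row1 - aa, col1 - aa
        dd = n - aa - bb - cc
        prob = np.exp(_log_table_prob(aa, bb, cc, dd))
        if sidedness == "greater":
            if aa >= a:
                p += prob
        else:  # two-sided: tables no more probable than observed
            if prob <= obs * (1 + 1e-12):
                p += prob
    return min(1.0, p)
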