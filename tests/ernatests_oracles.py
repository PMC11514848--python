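"""Independent brute-force oracles used by the test suite only.

These deliberately avoid the code paths (and, where possible, the libraries)
they are checking: the BH oracle is a literal quadratic step-up, and the
hypergeometric oracle sums exact rational tail terms with ``math.comb``.
"""

from fractions import Fraction
from math import comb

import numpy as np


def bh_quadratic_oracle(p):
    """Benjamini-Hochberg step-up, O(m^2): q_i = min over p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    ranks = np.array([np.sum(p <= p[i]) for i in range(m)])
    q = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(1.0, min(candidates))
    return q


def midrank_oracle(x):
    """Average ranks (1-based) computed by explicit tie-group averaging."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_rho_oracle(x, y):
    """Rank-then-Pearson: Pearson correlation of hand-computed mid-ranks."""
    return float(np.corrcoef(midrank_oracle(x), midrank_oracle(y))[0, 1])


def hypergeom_tail_table(N, K, n):
    """Exact upper-tail P(X >= k) for k = 0..min(n, K), via integer arithmetic."""
    kmax = min(n, K)
    nums = [comb(K, i) * comb(N - K, n - i) for i in range(kmax + 1)]
    denom = comb(N, n)
    tails = []
    running = 0
    for i in range(kmax, -1, -1):
        running += nums[i]
        tails.append(running / denom)
    return tails[::-1]  # tails[k] = P(X >= k)


def hypergeom_tail_exact(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational arithmetic."""
    if k <= 0:
        return 1.0
    denom = comb(N, n)
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return float(total)
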