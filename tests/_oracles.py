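"""Independent brute-force reference implementations used only by tests.

Each oracle follows the plain textbook definition with no shortcuts, so a
match with the package's (vectorized / library-backed) code is a genuine
dual-route check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats


def welch_oracle(a, b):
    """Welch statistic, Satterthwaite df and two-tailed p from first principles."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, min(p, 1.0)


def bh_oracle(pvalues, alpha=0.05):
    """Quadratic-time literal step-up rule: reject H_i iff p_i <= p_(k*) for
    the largest k* with p_(k*) <= k*.alpha/m."""
    p = list(map(float, pvalues))
    m = len(p)
    ordered = sorted(p)
    k_star = 0
    for k in range(1, m + 1):
        if ordered[k - 1] <= k * alpha / m:
            k_star = k
    if k_star == 0:
        return [False] * m
    threshold = ordered[k_star - 1]
    return [pi <= threshold for pi in p]


def average_linkage_oracle(d):
    """Agglomerative average linkage recomputing every cross-pair mean from
    the original grid at every step; ties broken by smallest sorted cluster
    member lists.  Returns [(set_a, set_b, height), ...]."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for ca, cb in combinations(sorted(clusters, key=lambda c: sorted(c)), 2):
            height = float(np.mean([d[i, j] for i in ca for j in cb]))
            key = (height, sorted(ca), sorted(cb))
            if best is None or key < best[0]:
                best = (key, ca, cb)
        (height, _, _), ca, cb = best
        merges.append((set(ca), set(cb), height))
        clusters = [c for c in clusters if c not in (ca, cb)] + [ca | cb]
    return merges


def hypergeom_upper_tail_oracle(k, N, K, n):
    """P[X >= k] for X ~ Hypergeometric(N, K, n) via explicit comb sums."""
    total = math.comb(N, n)
    upper = 0
    for x in range(k, min(K, n) + 1):
        if n - x > N - K:
            continue
        upper += math.comb(K, x) * math.comb(N - K, n - x)
    return upper / total


def trimmed_mean_oracle(values, fraction):
    """Sort, drop floor(fraction*m) from each end, average the rest."""
    ordered = sorted(map(float, values))
    k = math.floor(fraction * len(ordered))
    kept = ordered[k : len(ordered) - k] if k else ordered
    return sum(kept) / len(kept)
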