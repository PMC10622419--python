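"""Independent brute-force / closed-form oracles used by the tests.

These are deliberately naive implementations — enumeration, direct formulas,
grid optimization — kept free of any code path they are used to check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.optimize import minimize_scalar


def brute_force_consensus(runs, n):
    """Recount the consensus matrix from logged (subset, labels) pairs by
    iterating over every sample pair explicitly."""
    M = np.zeros((n, n))
    for i in range(n):
        M[i, i] = 1.0
        for j in range(i + 1, n):
            both = together = 0
            for subset, labels in runs:
                subset = list(subset)
                if i in subset and j in subset:
                    both += 1
                    if labels[subset.index(i)] == labels[subset.index(j)]:
                        together += 1
            M[i, j] = M[j, i] = together / both if both else 0.0
    return M


def exhaustive_two_partition(D):
    """Best 2-partition of n samples minimizing the summed within-group
    pairwise distance; n must be small (<= 12)."""
    n = len(D)
    best, best_cost = None, np.inf
    for size in range(1, n // 2 + 1):
        for group in combinations(range(n), size):
            g1 = set(group)
            cost = sum(D[i, j] for i in g1 for j in g1 if i < j)
            g2 = [i for i in range(n) if i not in g1]
            cost += sum(D[i, j] for i in g2 for j in g2 if i < j)
            if cost < best_cost:
                best_cost = cost
                best = np.array([0 if i in g1 else 1 for i in range(n)])
    return best


def logrank_two_group(t1, e1, t2, e2):
    """Two-group log-rank chi-square from the direct O-E formula."""
    t1, e1 = np.asarray(t1, float), np.asarray(e1, int)
    t2, e2 = np.asarray(t2, float), np.asarray(e2, int)
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O1 = E1 = V = 0.0
    for t in event_times:
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        d1 = np.sum((t1 == t) & (e1 == 1))
        d2 = np.sum((t2 == t) & (e2 == 1))
        n, d = n1 + n2, d1 + d2
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


def cox_beta_single(times, events, x):
    """Maximize the tie-free Cox partial likelihood for one covariate by
    direct 1-D optimization."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    assert len(np.unique(times)) == len(times), "oracle requires tie-free data"

    def neg_loglik(beta):
        ll = 0.0
        for i in np.where(events == 1)[0]:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    res = minimize_scalar(neg_loglik, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def fisher_2x2_enumeration(table):
    """Two-sided Fisher exact p by direct hypergeometric enumeration."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_p(k):
        return (math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
                + math.lgamma(r2 + 1) - math.lgamma(c1 - k + 1)
                - math.lgamma(r2 - c1 + k + 1)
                - (math.lgamma(n + 1) - math.lgamma(c1 + 1)
                   - math.lgamma(n - c1 + 1)))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = math.exp(log_p(a))
    total = 0.0
    for k in range(lo, hi + 1):
        pk = math.exp(log_p(k))
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


def hypergeom_tail(hits, M, K, n):
    """P(X >= hits) for X ~ Hypergeom(M, K, n) by direct summation."""
    def log_comb(a, b):
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    total = 0.0
    for k in range(hits, min(K, n) + 1):
        if n - k > M - K:
            continue
        total += math.exp(log_comb(K, k) + log_comb(M - K, n - k)
                          - log_comb(M, n))
    return min(1.0, total)


def km_by_hand(times, events):
    """Product-limit estimate at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = {}
    for t in np.unique(times[events == 1]):
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / n_at_risk
        out[float(t)] = s
    return out
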