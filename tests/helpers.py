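"""Independent oracles used by the test suite.

Everything here is deliberately written as direct, naive computation
(double loops, explicit entropy sums, exhaustive enumeration) so that it
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_modularity(adj: np.ndarray, labels) -> float:
    """Q = sum_ij [A_ij/(2m) - k_i k_j/(2m)^2] delta(c_i, c_j), directly."""
    labels = np.asarray(labels)
    two_m = adj.sum()
    k = adj.sum(axis=1)
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] / two_m - k[i] * k[j] / two_m**2
    return q


def all_partitions(n: int):
    """Every set partition of range(n), as label arrays (restricted growth)."""

    def rec(prefix, n_used):
        i = len(prefix)
        if i == n:
            yield np.array(prefix)
            return
        for lab in range(n_used + 1):
            yield from rec(prefix + [lab], max(n_used, lab + 1))

    yield from rec([], 0)


def max_modularity_exhaustive(adj: np.ndarray) -> float:
    return max(brute_modularity(adj, p) for p in all_partitions(adj.shape[0]))


def brute_nmi(p1, p2) -> float:
    """Explicit sum p log p over the confusion table, arithmetic-mean norm."""
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    n = p1.size
    cats1 = sorted(set(p1.tolist()))
    cats2 = sorted(set(p2.tolist()))
    nij = {}
    for a, b in zip(p1.tolist(), p2.tolist()):
        nij[(a, b)] = nij.get((a, b), 0) + 1
    na = {a: sum(v for (x, _), v in nij.items() if x == a) for a in cats1}
    nb = {b: sum(v for (_, y), v in nij.items() if y == b) for b in cats2}
    h1 = -sum((c / n) * math.log(c / n) for c in na.values() if c)
    h2 = -sum((c / n) * math.log(c / n) for c in nb.values() if c)
    if h1 == 0.0 and h2 == 0.0:
        return 1.0
    if h1 == 0.0 or h2 == 0.0:
        return 0.0
    mi = sum(
        (c / n) * math.log(c * n / (na[a] * nb[b])) for (a, b), c in nij.items() if c
    )
    return 2.0 * mi / (h1 + h2)


def by_stepup(p_values, alpha: float) -> np.ndarray:
    """Benjamini-Yekutieli step-up by direct enumeration of the rule:
    reject H_(1..k*) where k* is the largest k with
    p_(k) <= k * alpha / (m * c(m)), c(m) = sum_{i<=m} 1/i."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    cm = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / (m * cm):
            k_star = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    return rejected


def random_weighted_graph(rng: np.random.Generator, n: int, p_edge: float = 0.6):
    """Random symmetric positive-weight adjacency with at least one edge."""
    while True:
        adj = np.zeros((n, n))
        for i, j in combinations(range(n), 2):
            if rng.random() < p_edge:
                adj[i, j] = adj[j, i] = rng.uniform(0.1, 2.0)
        if adj.sum() > 0:
            return adj


def random_partition(rng: np.random.Generator, n: int, k_max: int) -> np.ndarray:
    k = int(rng.integers(1, k_max + 1))
    return rng.integers(0, k, size=n)
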