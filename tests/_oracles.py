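"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, O(n^3) agglomeration,
direct combinatorics) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def exhaustive_accumulation(presence: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean total/new gene counts over all G! genome orderings, by direct
    set accumulation."""
    g = presence.shape[0]
    total_sum = np.zeros(g)
    new_sum = np.zeros(g)
    n_orders = 0
    for order in itertools.permutations(range(g)):
        seen: set[int] = set()
        for step, idx in enumerate(order):
            genes = set(np.nonzero(presence[idx])[0])
            new = genes - seen
            seen |= genes
            new_sum[step] += len(new)
            total_sum[step] += len(seen)
        n_orders += 1
    return total_sum / n_orders, new_sum / n_orders


def naive_agglomerative(
    dist: np.ndarray, method: str
) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) agglomeration on a full distance matrix.

    Returns the merge list [(cluster_a, cluster_b, height), ...] in merge
    order.  ``method`` is "single", "complete" or "average"; cluster-pair
    distances are recomputed from the original matrix at every step.
    """
    n = dist.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges: list[tuple[frozenset, frozenset, float]] = []

    def cluster_dist(a: frozenset, b: frozenset) -> float:
        values = [dist[i, j] for i in a for j in b]
        if method == "single":
            return min(values)
        if method == "complete":
            return max(values)
        return sum(values) / len(values)

    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(range(len(clusters)), 2):
            d = cluster_dist(clusters[x], clusters[y])
            if best is None or d < best[0]:
                best = (d, x, y)
        d, x, y = best
        a, b = clusters[x], clusters[y]
        merges.append((a, b, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(a | b)
    return merges


def naive_cut(dist: np.ndarray, threshold: float, method: str) -> list[set]:
    """Flat clusters from naive agglomeration: merge while the cluster-pair
    distance is <= threshold."""
    n = dist.shape[0]
    clusters: list[set] = [{i} for i in range(n)]

    def cluster_dist(a: set, b: set) -> float:
        values = [dist[i, j] for i in a for j in b]
        if method == "single":
            return min(values)
        if method == "complete":
            return max(values)
        return sum(values) / len(values)

    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(range(len(clusters)), 2):
            d = cluster_dist(clusters[x], clusters[y])
            if best is None or d < best[0]:
                best = (d, x, y)
        d, x, y = best
        if d > threshold:
            break
        merged = clusters[x] | clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)
    return clusters


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by direct summation of
    binomial coefficients."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / total


def hypergeom_by_enumeration(universe: list, carriers: set, draw: set) -> float:
    """P(X >= observed) by enumerating every possible draw of |draw| genes
    from the universe.  Only feasible for tiny universes."""
    k_obs = len(carriers & draw)
    n = len(draw)
    hits = 0
    total = 0
    for combo in itertools.combinations(universe, n):
        total += 1
        if len(carriers & set(combo)) >= k_obs:
            hits += 1
    return hits / total


def textbook_bh(p: list[float]) -> list[float]:
    """Step-up Benjamini-Hochberg written directly from the textbook
    definition, one rank at a time."""
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = min(val, 1.0)
        prev = val
    return q


def bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    num = 2.0 * np.minimum(x, y).sum()
    den = x.sum() + y.sum()
    return 1.0 - num / den if den > 0 else 0.0
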