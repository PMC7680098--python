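"""Independent brute-force oracles used to validate the implementation.

These are deliberately naive (enumeration, O(n^3) loops) and share no code
with the package paths they check.
"""

from itertools import combinations

import numpy as np


def brute_force_linkage_heights(dist: np.ndarray, method: str) -> list[float]:
    """O(n^3) agglomerative clustering; returns the sorted merge heights.

    Clusters are merged greedily at the smallest inter-cluster distance,
    where the inter-cluster distance is the max (complete), mean (average)
    or min (single) of the member pair distances.
    """
    n = dist.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights = []
    combine = {"complete": max, "single": min,
               "average": lambda v: sum(v) / len(v)}[method]
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = combine([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


def brute_force_cophenetic(dist: np.ndarray, method: str) -> np.ndarray:
    """O(n^3) agglomeration returning the pairwise merge-height matrix."""
    n = dist.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    coph = np.zeros((n, n))
    combine = {"complete": max, "single": min,
               "average": lambda v: sum(v) / len(v)}[method]
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = combine([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return coph


def exact_rank_sum_p(x, y) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of all C(n+m, n) splits.

    Computes the permutation distribution of the Mann-Whitney U of the first
    sample and returns 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    x = list(x)
    y = list(y)
    pooled = np.array(x + y, dtype=float)
    n = len(x)
    idx_all = range(len(pooled))

    def u_stat(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(range(n))
    us = [u_stat(c) for c in combinations(idx_all, n)]
    us = np.array(us)
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return float(min(1.0, 2 * min(p_le, p_ge)))


def brute_force_min_within_between(dist: np.ndarray, sample_circles: list):
    """Exhaustive pair scan for per-circle and per-circle-pair minimum distances."""
    circles = list(dict.fromkeys(sample_circles))
    n = len(sample_circles)
    within = {}
    between = {}
    for c in circles:
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                if sample_circles[i] == c and sample_circles[j] == c:
                    if best is None or dist[i, j] < best:
                        best = dist[i, j]
        if best is not None:
            within[c] = best
    for a, b in combinations(circles, 2):
        best = None
        for i in range(n):
            for j in range(n):
                if sample_circles[i] == a and sample_circles[j] == b:
                    if best is None or dist[i, j] < best:
                        best = dist[i, j]
        between[(a, b)] = best
    return within, between
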