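"""Brute-force reference implementations used to cross-check the package.

These deliberately use the most literal formulation of each quantity —
quadratic pairwise loops, exhaustive enumeration, numerical quadrature —
and stay independent of the code paths they validate.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate


def silhouette_bruteforce(values: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette from explicit pairwise Euclidean distances."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = math.sqrt(((values[i] - values[j]) ** 2).sum())
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = sum(dist[i, j] for j in same) / len(same)
        b = min(
            sum(dist[i, j] for j in range(n) if labels[j] == other)
            / sum(1 for j in range(n) if labels[j] == other)
            for other in set(labels) - {labels[i]}
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def calinski_harabasz_bruteforce(values: np.ndarray, labels: np.ndarray) -> float:
    """(SSB/(k-1)) / (SSW/(n-k)) from explicit dispersion sums."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    clusters = sorted(set(labels.tolist()))
    k = len(clusters)
    grand = values.mean(axis=0)
    ssb = ssw = 0.0
    for c in clusters:
        pts = values[labels == c]
        centroid = pts.mean(axis=0)
        ssb += len(pts) * float(((centroid - grand) ** 2).sum())
        ssw += float(((pts - centroid) ** 2).sum())
    return (ssb / (k - 1)) / (ssw / (n - k))


def welch_bruteforce(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch t, df and two-tailed p with the p from quadrature of the t density."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    v1 = sum((xi - x.mean()) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - y.mean()) ** 2 for yi in y) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))

    def t_density(u: float) -> float:
        return (
            math.gamma((df + 1) / 2)
            / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            * (1 + u**2 / df) ** (-(df + 1) / 2)
        )

    tail, _ = integrate.quad(t_density, abs(t), np.inf)
    return t, df, 2.0 * tail


def hypergeom_tail_bruteforce(k: int, n_universe: int, set_size: int, n_query: int) -> float:
    """P[overlap >= k] by exhaustive enumeration of all query draws."""
    universe = range(n_universe)
    members = set(range(set_size))
    hits = total = 0
    for draw in itertools.combinations(universe, n_query):
        total += 1
        if len(members.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Step-up BH: m*p/i with a running minimum from the largest p down."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running = min(running, m * p[idx] / (rank_from_top + 1))
        adjusted[idx] = running
    return adjusted
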