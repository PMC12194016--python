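"""Brute-force oracles used by the statistics tests.

Deliberately naive O(n^3) implementations written straight from the
definitions, independent of scipy/sklearn code paths.
"""

from __future__ import annotations

import numpy as np


def ward_merge_heights(X: np.ndarray) -> list[float]:
    """Greedy Ward agglomeration heights, sqrt(2 * increase in SSE).

    At each step merge the cluster pair whose merge increases the total
    within-cluster sum of squares the least; the recorded height is
    sqrt(2 * delta SSE), which for singletons reduces to the Euclidean
    distance.
    """
    clusters = [[i] for i in range(len(X))]
    heights: list[float] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                ca = X[a].mean(axis=0)
                cb = X[b].mean(axis=0)
                d_sse = (len(a) * len(b)) / (len(a) + len(b)) * float(
                    np.sum((ca - cb) ** 2)
                )
                cost = np.sqrt(2.0 * d_sse)
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        cost, i, j = best
        heights.append(cost)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


def silhouette_mean(X: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width straight from the definition."""
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    widths = []
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            widths.append(0.0)
            continue
        a = D[i, own & (np.arange(n) != i)].mean()
        b = min(
            D[i, labels == lab].mean() for lab in np.unique(labels) if lab != labels[i]
        )
        widths.append((b - a) / max(a, b))
    return float(np.mean(widths))
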