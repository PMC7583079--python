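"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np


def naive_agglomeration(X, K, linkage="average"):
    """From-scratch agglomeration recomputing all merge distances naively."""
    clusters = [[i] for i in range(len(X))]
    d = lambda a, b: np.linalg.norm(X[a] - X[b])
    agg = max if linkage == "complete" else (lambda v: sum(v) / len(v))
    while len(clusters) > K:
        best, pair = None, None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            val = agg([d(a, b) for a in clusters[i] for b in clusters[j]])
            if best is None or val < best:
                best, pair = val, (i, j)
        i, j = pair
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(len(X), dtype=int)
    for k, members in enumerate(clusters):
        labels[members] = k
    return labels


def dtw_bruteforce(a, b):
    """Enumerate all monotone warping paths on a tiny grid."""
    n = len(a)
    best = [np.inf]

    def walk(i, j, cost):
        cost = cost + (a[i] - b[j]) ** 2
        if i == n - 1 and j == n - 1:
            best[0] = min(best[0], cost)
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            if i + di < n and j + dj < n:
                walk(i + di, j + dj, cost)

    walk(0, 0, 0.0)
    return np.sqrt(best[0])
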