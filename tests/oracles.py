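"""Independent brute-force reference implementations used only by tests.

These deliberately use naive loops and exhaustive search so that they share no
code path with the package implementations they check.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def hoeffding_d_brute(x, y) -> float:
    """Hoeffding's D via explicit loops over concordance indicators.

    Univariate and bivariate ranks are accumulated pairwise (ties counted
    half), and the three sums of the 1948 statistic are evaluated directly.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    Q = np.empty(n)
    R = np.empty(n)
    S = np.empty(n)
    for i in range(n):
        q = r = s = 0.0
        for j in range(n):
            if j == i:
                continue
            r += (x[j] < x[i]) + 0.5 * (x[j] == x[i])
            s += (y[j] < y[i]) + 0.5 * (y[j] == y[i])
            q += (
                (x[j] < x[i]) * (y[j] < y[i])
                + 0.5 * ((x[j] == x[i]) * (y[j] < y[i]) + (x[j] < x[i]) * (y[j] == y[i]))
                + 0.25 * ((x[j] == x[i]) * (y[j] == y[i]))
            )
        Q[i] = 1 + q
        R[i] = 1 + r
        S[i] = 1 + s
    d1 = float(np.sum((Q - 1) * (Q - 2)))
    d2 = float(np.sum((R - 1) * (R - 2) * (S - 1) * (S - 2)))
    d3 = float(np.sum((R - 2) * (S - 2) * (Q - 1)))
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return 30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / denom


def ward_heights_brute(points: np.ndarray) -> np.ndarray:
    """Agglomerate by recomputing the within-group SS increment

        I_AB = n_A n_B / (n_A + n_B) * ||mean_A - mean_B||^2

    from the raw points at every stage, merging the minimal pair."""
    points = np.asarray(points, float)
    clusters = [[i] for i in range(points.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pa = points[clusters[a]]
                pb = points[clusters[b]]
                na, nb = len(pa), len(pb)
                diff = pa.mean(axis=0) - pb.mean(axis=0)
                inc = na * nb / (na + nb) * float(diff @ diff)
                if best is None or inc < best[0]:
                    best = (inc, a, b)
        inc, a, b = best
        heights.append(inc)
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return np.asarray(heights)


def ccr_brute(truth, predicted) -> float:
    """Maximum agreement fraction over all one-to-one label mappings,
    found by exhaustive search over permutations."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    t_labels = list(np.unique(truth))
    p_labels = list(np.unique(predicted))
    n = len(truth)
    best = 0
    if len(p_labels) <= len(t_labels):
        for assign in permutations(t_labels, len(p_labels)):
            matched = sum(
                int(np.sum((predicted == p) & (truth == t)))
                for p, t in zip(p_labels, assign)
            )
            best = max(best, matched)
    else:
        for assign in permutations(p_labels, len(t_labels)):
            matched = sum(
                int(np.sum((predicted == p) & (truth == t)))
                for t, p in zip(t_labels, assign)
            )
            best = max(best, matched)
    return best / n
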