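"""Independent brute-force oracles used to validate the dynamic programs.

These deliberately share no code with the package implementations: costs
are computed by direct two-pass means, partitions by exhaustive
enumeration or a plain O(P^2) Bellman recursion.
"""

import itertools

import numpy as np


def direct_sse(y, i, j):
    """Two-pass SSE of y[i..j] (0-based inclusive)."""
    seg = np.asarray(y, dtype=float)[i : j + 1]
    return float(((seg - seg.mean()) ** 2).sum())


def best_partition_exhaustive(y, K):
    """Globally best K-segmentation by enumerating all compositions.

    Returns (sse, ends) with 1-based segment end indices.
    """
    y = np.asarray(y, dtype=float)
    P = len(y)
    best_sse, best_ends = np.inf, None
    for cuts in itertools.combinations(range(1, P), K - 1):
        ends = list(cuts) + [P]
        starts = [0] + list(cuts)
        sse = sum(direct_sse(y, s, e - 1) for s, e in zip(starts, ends))
        if sse < best_sse - 1e-12:
            best_sse, best_ends = sse, ends
    return best_sse, np.array(best_ends)


def penalized_partition_dp(y, beta):
    """Unpruned optimal partitioning for cost SSE + beta per segment.

    Plain O(P^2) Bellman recursion with direct cost evaluation; returns
    1-based segment ends.
    """
    y = np.asarray(y, dtype=float)
    P = len(y)
    cum = np.concatenate(([0.0], np.cumsum(y)))
    cum2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def cost(a, b):  # 0-based half-open [a, b)
        n = b - a
        s = cum[b] - cum[a]
        return (cum2[b] - cum2[a]) - s * s / n

    F = np.full(P + 1, np.inf)
    F[0] = 0.0
    prev = np.zeros(P + 1, dtype=int)
    for t in range(1, P + 1):
        for a in range(t):
            val = F[a] + cost(a, t) + beta
            if val < F[t] - 1e-12:
                F[t] = val
                prev[t] = a
    ends = []
    t = P
    while t > 0:
        ends.append(t)
        t = prev[t]
    return np.array(ends[::-1])


def soft_threshold(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)
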