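"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive search rather than by
the package's own algorithms.
"""

from __future__ import annotations

import numpy as np


def density_sweep_segments(positions, counts) -> set[tuple[int, int]]:
    """All distinct maximal positive-scoring segments over a density sweep.

    For a density penalty d, a segment scores ``total_count - d * span``.
    The maximal segments at penalty d are found by exhaustively scanning all
    O(n^2) segments: take the best-scoring segment (leftmost, then shortest,
    on ties), then recurse on what remains to its left and right. Sweeping d
    over midpoints between all critical boundary densities (plus one value
    below and one above the critical range) enumerates every segment that is
    maximal for some d. Returned as (start_position, end_position_exclusive).
    """
    pos = np.asarray(positions, dtype=np.int64)
    cnt = np.asarray(counts, dtype=np.int64)
    n = pos.size
    if n == 0:
        return set()
    csum = np.concatenate([[0], np.cumsum(cnt)])
    total = csum[None, 1:] - csum[:-1, None]        # total[i, j] (j >= i)
    span = (pos[None, :] - pos[:, None]).astype(float)

    crit = set()
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(i + 1, j + 1):
                crit.add((csum[k] - csum[i]) / (pos[k] - pos[i]))
            for k in range(i, j):
                crit.add((csum[j + 1] - csum[k + 1]) / (pos[j] - pos[k]))
    crit = sorted(crit)
    if crit:
        sweep = [crit[0] / 2.0]
        sweep.extend((a + b) / 2.0 for a, b in zip(crit, crit[1:]))
        sweep.append(crit[-1] + 1.0)
    else:
        sweep = [1.0]

    upper = np.triu(np.ones((n, n), dtype=bool))
    found: set[tuple[int, int]] = set()
    for d in sweep:
        score = np.where(upper, total - d * span, -np.inf)
        stack = [(0, n - 1)]
        while stack:
            lo, hi = stack.pop()
            if lo > hi:
                continue
            sub = score[lo:hi + 1, lo:hi + 1]
            best = np.max(sub)
            if best <= 0:
                continue
            ii, jj = np.argwhere(sub == best)[0]    # leftmost, then shortest
            i, j = lo + int(ii), lo + int(jj)
            found.add((int(pos[i]), int(pos[j]) + 1))
            stack.append((lo, i - 1))
            stack.append((j + 1, hi))
    return found


def exhaustive_ward_partitions(points) -> dict[int, set[frozenset[int]]]:
    """Ward's minimum-variance agglomeration by exhaustive pair search.

    At each step evaluates every cluster pair's increase in within-cluster
    sum of squares, |A||B|/(|A|+|B|) * ||mean_A - mean_B||^2, and merges the
    minimum (smallest pair index on ties). Returns the partition at every
    cut level k.
    """
    X = np.asarray(points, dtype=float)
    clusters: list[list[int]] = [[i] for i in range(len(X))]
    partitions = {len(clusters): {frozenset(c) for c in clusters}}
    while len(clusters) > 1:
        best, best_pair = np.inf, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ma = X[clusters[a]].mean(axis=0)
                mb = X[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                inc = na * nb / (na + nb) * float(np.sum((ma - mb) ** 2))
                if inc < best:
                    best, best_pair = inc, (a, b)
        a, b = best_pair
        merged = clusters[a] + clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)]
        clusters.append(merged)
        partitions[len(clusters)] = {frozenset(c) for c in clusters}
    return partitions
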