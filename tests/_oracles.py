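"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity from first principles, deliberately
avoiding the vectorized/library code paths used by the package.
"""
from __future__ import annotations

from math import comb

import numpy as np


def de_oracle(values, stages, direction):
    """Discriminating error by exhaustive enumeration.

    Every sample value (plus one sentinel above the maximum) is tried as a
    threshold at every ordered stage split; errors are counted directly.
    """
    vals = [float(v) for v in values]
    if direction == "ascending":
        vals = [-v for v in vals]
    T = max(stages)
    per_split = []
    for k in range(1, T):
        early = [v for v, s in zip(vals, stages) if s <= k]
        late = [v for v, s in zip(vals, stages) if s > k]
        candidates = sorted(set(vals)) + [max(vals) + 1.0]
        best = min(
            sum(v < t for v in early) + sum(v >= t for v in late)
            for t in candidates
        )
        per_split.append(best)
    return sum(per_split), per_split


def tmm_oracle(counts, ref, trim_m=0.30, trim_a=0.05):
    """TMM factors applied step by step, literally, with plain loops.

    counts: 2d array genes x samples; ref: reference column index.
    Returns factors rescaled to geometric mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    lib = [sum(counts[:, j]) for j in range(n_samples)]
    factors = []
    for j in range(n_samples):
        if j == ref:
            factors.append(1.0)
            continue
        m_vals, a_vals, weights = [], [], []
        for g in range(n_genes):
            pj = counts[g, j] / lib[j]
            pr = counts[g, ref] / lib[ref]
            m_vals.append(np.log2(pj / pr))
            a_vals.append(0.5 * np.log2(pj * pr))
            w = 1.0 / (
                (lib[j] - counts[g, j]) / (lib[j] * counts[g, j])
                + (lib[ref] - counts[g, ref]) / (lib[ref] * counts[g, ref])
            )
            weights.append(w)
        n = n_genes
        lo_m, hi_m = int(np.floor(n * trim_m)), n - int(np.floor(n * trim_m))
        lo_a, hi_a = int(np.floor(n * trim_a)), n - int(np.floor(n * trim_a))
        m_rank = {g: r for r, g in enumerate(sorted(range(n), key=lambda g: m_vals[g]))}
        a_rank = {g: r for r, g in enumerate(sorted(range(n), key=lambda g: a_vals[g]))}
        kept = [
            g
            for g in range(n)
            if lo_m <= m_rank[g] < hi_m and lo_a <= a_rank[g] < hi_a
        ]
        if kept:
            num = sum(weights[g] * m_vals[g] for g in kept)
            den = sum(weights[g] for g in kept)
            factors.append(2.0 ** (num / den))
        else:
            factors.append(1.0)
    log_mean = np.mean([np.log(f) for f in factors])
    return [f / np.exp(log_mean) for f in factors]


def hypergeom_upper_tail(N, K, n, k):
    """P(X >= k) for X ~ Hypergeom(N, K, n), by exact combinatorial sums."""
    total = comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            acc += comb(K, i) * comb(N - K, n - i)
    return acc / total


def bfs_levels_oracle(adjacency, seed):
    """Level = shortest-path distance + 1, via Floyd-Warshall on the
    adjacency dict; unreachable nodes omitted."""
    nodes = sorted(adjacency)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    inf = float("inf")
    dist = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for u, nbrs in adjacency.items():
        for v in nbrs:
            dist[idx[u]][idx[v]] = 1
            dist[idx[v]][idx[u]] = 1
    for m in range(n):
        for i in range(n):
            for j in range(n):
                d = dist[i][m] + dist[m][j]
                if d < dist[i][j]:
                    dist[i][j] = d
    s = idx[seed]
    return {v: int(dist[s][idx[v]]) + 1 for v in nodes if dist[s][idx[v]] < inf}
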