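"""Independently coded brute-force oracles for the graph and rank statistics.

Deliberately naive: pure-Python Floyd-Warshall, pair enumeration and
sign-assignment enumeration, sharing no code with the package paths they
check.
"""

from __future__ import annotations

import itertools
import math


def floyd_warshall(lengths: list[list[float]]) -> list[list[float]]:
    """All-pairs shortest paths; input uses math.inf for missing edges."""
    n = len(lengths)
    d = [[lengths[i][j] if i != j else 0.0 for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                alt = d[i][k] + d[k][j]
                if alt < d[i][j]:
                    d[i][j] = alt
    return d


def _sub_lengths(lengths, idx):
    return [[lengths[a][b] for b in idx] for a in idx]


def char_path_length(lengths, idx) -> tuple[float | None, int]:
    """Mean finite shortest-path length over ordered pairs of idx."""
    if len(idx) < 2:
        return None, 0
    d = floyd_warshall(_sub_lengths(lengths, idx))
    vals = [d[i][j] for i in range(len(idx)) for j in range(len(idx)) if i != j]
    finite = [v for v in vals if math.isfinite(v)]
    if not finite:
        return None, len(vals)
    return sum(finite) / len(finite), len(vals) - len(finite)


def global_efficiency(lengths, idx) -> float | None:
    if len(idx) < 2:
        return None
    d = floyd_warshall(_sub_lengths(lengths, idx))
    total, count = 0.0, 0
    for i in range(len(idx)):
        for j in range(len(idx)):
            if i == j:
                continue
            count += 1
            if math.isfinite(d[i][j]) and d[i][j] > 0:
                total += 1.0 / d[i][j]
    return total / count


def local_efficiency(adj: list[list[float]], node: int) -> float:
    """Efficiency of the neighbor-induced subgraph on max-normalized weights."""
    n = len(adj)
    wmax = max(adj[i][j] for i in range(n) for j in range(n))
    if wmax <= 0:
        return 0.0
    W = [[adj[i][j] / wmax for j in range(n)] for i in range(n)]
    nbrs = [j for j in range(n) if W[node][j] > 0 and j != node]
    if len(nbrs) < 2:
        return 0.0
    lengths = [[(1.0 / W[i][j]) if W[i][j] > 0 else math.inf for j in range(n)]
               for i in range(n)]
    return global_efficiency(lengths, nbrs)


def graph_radius_complete(weights: list[list[float]]) -> float:
    """Radius of a complete weighted graph (weights are path lengths)."""
    n = len(weights)
    if n == 1:
        return 0.0
    d = floyd_warshall(weights)
    return min(max(d[i][j] for j in range(n)) for i in range(n))


def signrank_exact_p(diffs: list[float]) -> float:
    """Two-sided exact signed-rank p by enumeration of all sign vectors."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    absd = sorted((abs(x), i) for i, x in enumerate(d))
    # midranks
    ranks = [0.0] * n
    i = 0
    pos = 0
    while i < n:
        j = i
        while j < n and absd[j][0] == absd[i][0]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[absd[k][1]] = mid
        i = j
        pos = j
    assert pos == n
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    le = ge = total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le / total, ge / total))
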