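"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: a plain full-matrix
Smith-Waterman (Gotoh) scorer, an exact Mann-Whitney enumeration, a
midrank-then-Pearson Spearman, and a shortest-path-enumeration
betweenness counter.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import networkx as nx
import numpy as np


def smith_waterman_score(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> int:
    """Best local affine-gap alignment score by full-matrix Gotoh DP.

    A gap of length L scores gap_open + L * gap_extend.  N never
    matches anything.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            s = match if (ai == bj and ai != "N") else mismatch
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend,
                          E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend,
                          F[i - 1][j] + gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


def mann_whitney_exact_two_sided(x, y) -> tuple[float, float]:
    """(U of x, exact two-sided p) by enumerating all rank assignments.

    Assumes tie-free pooled data.  Exploits the symmetry of the null
    distribution of U around n*m/2: the two-sided p-value is the null
    probability of a U at least as far from n*m/2 as the observed one.
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n, m = len(x), len(y)
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    center = n * m / 2
    dev = abs(u_obs - center)
    total = comb(n + m, n)
    hits = 0
    all_ranks = list(range(1, n + m + 1))
    for combo in combinations(all_ranks, n):
        u = sum(combo) - n * (n + 1) / 2
        if abs(u - center) >= dev - 1e-12:
            hits += 1
    return float(u_obs), hits / total


def spearman_oracle(x, y) -> float:
    """Spearman rho as Pearson correlation of explicitly computed midranks."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def betweenness_by_path_enumeration(graph: nx.Graph) -> dict:
    """Pair-counting betweenness via explicit shortest-path enumeration."""
    counts = {v: 0 for v in graph.nodes}
    nodes = list(graph.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if not nx.has_path(graph, s, t):
                continue
            interior = set()
            for path in nx.all_shortest_paths(graph, s, t):
                interior.update(path[1:-1])
            for v in interior:
                counts[v] += 1
    return counts
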