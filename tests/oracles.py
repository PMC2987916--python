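"""Independent brute-force reference implementations used only by tests.

Everything here works by exhaustive enumeration with exact (Fraction)
arithmetic on tiny graphs, deliberately avoiding the algorithms used in the
package (no BFS/Brandes, no matrix products): distances come from
enumerating all simple paths, betweenness from counting the enumerated
shortest paths explicitly.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np


def enumerate_simple_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """All simple s→t paths, as node tuples including both endpoints."""
    n = adj.shape[0]
    out: list[tuple[int, ...]] = []

    def walk(path: list[int]) -> None:
        u = path[-1]
        if u == t:
            out.append(tuple(path))
            return
        for v in range(n):
            if adj[u, v] and v not in path:
                walk(path + [v])

    walk([s])
    return out


def brute_clustering(adj: np.ndarray) -> list[Fraction]:
    """Exact per-node clustering by enumerating neighbor pairs."""
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            cs.append(Fraction(0))
        else:
            e = sum(1 for u, v in combinations(nb, 2) if adj[u, v])
            cs.append(Fraction(2 * e, k * (k - 1)))
    return cs


def brute_cp(adj: np.ndarray) -> Fraction:
    cs = brute_clustering(adj)
    return sum(cs, Fraction(0)) / len(cs)


def brute_distances(adj: np.ndarray) -> dict[tuple[int, int], int]:
    """Exact pairwise distances from exhaustive simple-path enumeration."""
    n = adj.shape[0]
    d = {}
    for s, t in combinations(range(n), 2):
        paths = enumerate_simple_paths(adj, s, t)
        assert paths, "oracle requires a connected graph"
        d[(s, t)] = min(len(p) - 1 for p in paths)
    return d


def brute_lp(adj: np.ndarray) -> Fraction:
    """Exact characteristic path length (mean over nodes of mean distance)."""
    n = adj.shape[0]
    d = brute_distances(adj)
    total = Fraction(0)
    for i in range(n):
        row = sum(d[(min(i, j), max(i, j))] for j in range(n) if j != i)
        total += Fraction(row, n - 1)
    return total / n


def brute_betweenness(adj: np.ndarray) -> list[Fraction]:
    """Exact fractional-credit betweenness from enumerated shortest paths."""
    n = adj.shape[0]
    b = [Fraction(0) for _ in range(n)]
    for s, t in combinations(range(n), 2):
        paths = enumerate_simple_paths(adj, s, t)
        dmin = min(len(p) - 1 for p in paths)
        shortest = [p for p in paths if len(p) - 1 == dmin]
        sigma = len(shortest)
        for i in range(n):
            if i in (s, t):
                continue
            through = sum(1 for p in shortest if i in p[1:-1])
            if through:
                b[i] += Fraction(through, sigma)
    return b


def brute_pearson(x, y) -> float:
    """Textbook Pearson formula: sums only, no library calls."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(u * v for u, v in zip(x, y))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den


def random_connected_graph(rng: np.random.Generator, n_max: int = 7) -> np.ndarray:
    """Uniform-ish random connected simple graph with 3..n_max nodes."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        p = float(rng.uniform(0.3, 0.9))
        adj = np.triu((rng.random((n, n)) < p), k=1)
        adj = adj | adj.T
        # connectivity via exhaustive reachability (no BFS library)
        reach = {0}
        frontier = {0}
        while frontier:
            nxt = {v for u in frontier for v in range(n) if adj[u, v] and v not in reach}
            reach |= nxt
            frontier = nxt
        if len(reach) == n:
            return adj.astype(bool)
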