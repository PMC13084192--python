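"""Independent brute-force evaluators of the graph formulas.

Deliberately naive: Floyd-Warshall distances, explicit loops, direct
translation of each defining formula.  Shares no code with the package so
it can serve as an oracle for it.
"""

from __future__ import annotations

import itertools

import numpy as np

INF = float("inf")


def fw_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest hop counts by Floyd-Warshall."""
    n = adj.shape[0]
    d = np.full((n, n), INF)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def char_path_length(adj: np.ndarray) -> tuple[float, float]:
    """(L over connected ordered pairs, connected pair fraction)."""
    d = fw_distances(adj)
    n = adj.shape[0]
    vals, total = [], 0
    for i in range(n):
        for j in range(n):
            if i != j:
                total += 1
                if d[i, j] < INF:
                    vals.append(d[i, j])
    frac = len(vals) / total if total else 0.0
    return (sum(vals) / len(vals) if vals else float("nan")), frac


def global_efficiency(adj: np.ndarray) -> float:
    d = fw_distances(adj)
    n = adj.shape[0]
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and d[i, j] < INF:
                acc += 1.0 / d[i, j]
    return acc / (n * (n - 1)) if n > 1 else 0.0


def degrees(adj: np.ndarray) -> list[int]:
    return [int(adj[i].sum()) for i in range(adj.shape[0])]


def clustering(adj: np.ndarray) -> list[float]:
    """C_X = 2 E_X / (D_X (D_X - 1)) with E_X counted by pair enumeration."""
    n = adj.shape[0]
    out = []
    for x in range(n):
        nbrs = [j for j in range(n) if adj[x, j]]
        d = len(nbrs)
        if d < 2:
            out.append(0.0)
            continue
        e = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b])
        out.append(2.0 * e / (d * (d - 1)))
    return out


def _geodesic_counts(adj: np.ndarray, d: np.ndarray, src: int) -> np.ndarray:
    """sigma[src, v]: number of shortest paths from src to every v, by
    dynamic programming over increasing distance."""
    n = adj.shape[0]
    sigma = np.zeros(n)
    sigma[src] = 1.0
    reachable = [v for v in range(n) if d[src, v] < INF]
    for v in sorted(reachable, key=lambda v: d[src, v]):
        if v == src:
            continue
        sigma[v] = sum(sigma[u] for u in range(n)
                       if adj[u, v] and d[src, u] == d[src, v] - 1)
    return sigma


def betweenness(adj: np.ndarray) -> list[float]:
    """B_X over unordered pairs {Y,Z}, endpoints excluded, unnormalised."""
    n = adj.shape[0]
    d = fw_distances(adj)
    sigma = np.vstack([_geodesic_counts(adj, d, s) for s in range(n)])
    out = []
    for x in range(n):
        acc = 0.0
        for y in range(n):
            for z in range(y + 1, n):
                if x in (y, z) or d[y, z] == INF:
                    continue
                # shortest paths through x: must enter and leave x on geodesics
                if d[y, x] + d[x, z] == d[y, z]:
                    acc += sigma[y, x] * sigma[x, z] / sigma[y, z]
        out.append(acc)
    return out


def betweenness_by_path_enumeration(adj: np.ndarray) -> list[float]:
    """B_X by exhaustively enumerating every simple path (n <= 8 only)."""
    n = adj.shape[0]
    d = fw_distances(adj)
    geodesics: dict[tuple[int, int], list[tuple[int, ...]]] = {}
    for y in range(n):
        for z in range(y + 1, n):
            if d[y, z] == INF:
                continue
            target_len = int(d[y, z])
            found = []

            def extend(path):
                last = path[-1]
                if last == z:
                    if len(path) - 1 == target_len:
                        found.append(tuple(path))
                    return
                if len(path) - 1 >= target_len:
                    return
                for w in range(n):
                    if adj[last, w] and w not in path:
                        extend(path + [w])

            extend([y])
            geodesics[(y, z)] = found
    out = []
    for x in range(n):
        acc = 0.0
        for (y, z), paths in geodesics.items():
            if x in (y, z) or not paths:
                continue
            acc += sum(1 for p in paths if x in p) / len(paths)
        out.append(acc)
    return out


def local_efficiency(adj: np.ndarray) -> list[float]:
    """Ordered-pair average of 1/l within each node's neighbour subgraph."""
    n = adj.shape[0]
    out = []
    for x in range(n):
        nbrs = [j for j in range(n) if adj[x, j]]
        m = len(nbrs)
        if m < 2:
            out.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        d = fw_distances(sub)
        acc = 0.0
        for a in range(m):
            for b in range(m):
                if a != b and d[a, b] < INF:
                    acc += 1.0 / d[a, b]
        out.append(acc / (m * (m - 1)))
    return out


def ols_slope_intercept(x, y) -> tuple[float, float]:
    """Textbook least squares on (x, y) with intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    k = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    return k, ym - k * xm


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Erdos-Renyi adjacency matrix."""
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T
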