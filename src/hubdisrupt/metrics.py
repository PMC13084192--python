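"""Global and nodal graph-theoretic metrics on binary networks.

Global: characteristic path length L, global efficiency E_glob, mean
clustering coefficient C.  Nodal: degree D_X, clustering C_X, betweenness
B_X, local efficiency E_loc(X).  All distances are unweighted hop counts.

Conventions (each one tested):

* L averages over *connected* ordered pairs only; the fraction of connected
  pairs is reported alongside so the choice is visible.  At the sparsities
  used here (>= 0.2) networks are almost always connected, so this rarely
  binds.
* E_glob averages 1/l over all ordered pairs with 1/inf = 0.
* Betweenness counts each unordered pair {Y, Z} once, endpoints excluded,
  with no normalising factor.  (An ordered-pair convention is exactly 2x
  and cancels in any slope fitted on these values.)
* C_X and E_loc(X) are 0 for nodes of degree < 2, where the defining
  ratios degenerate.
* E_loc(X) is the ordered-pair average of 1/l(Y, Z) over X's neighbours,
  with distances measured inside the subgraph induced on the neighbours
  (X itself removed).
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.sparse.csgraph import shortest_path

from .containers import BinaryNetwork, GlobalMetrics, NodalMetrics


def shortest_path_lengths(net: BinaryNetwork) -> np.ndarray:
    """All-pairs unweighted distances; unreachable pairs are ``inf``."""
    return shortest_path(net.adjacency, method="D", unweighted=True, directed=False)


def _pathlength_stats(dist: np.ndarray) -> tuple[float, float, float]:
    """(L, E_glob, connected fraction) from a distance matrix."""
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    d = dist[off]
    finite = np.isfinite(d)
    frac = float(finite.mean()) if d.size else 0.0
    e_glob = float(np.sum(1.0 / d[finite]) / d.size) if d.size else 0.0
    if not finite.any():
        l = float("nan")
    else:
        l = float(d[finite].mean())
    return l, e_glob, frac


def characteristic_path_length(net: BinaryNetwork) -> float:
    """Mean hop distance over connected ordered node pairs."""
    l, _, frac = _pathlength_stats(shortest_path_lengths(net))
    if frac == 0.0:
        raise ValueError("no connected pairs: characteristic path length undefined")
    return l


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean inverse hop distance over all ordered pairs (1/inf = 0)."""
    _, e_glob, _ = _pathlength_stats(shortest_path_lengths(net))
    return e_glob


def degree_centrality(net: BinaryNetwork) -> np.ndarray:
    """Edge count per region (row sums of the adjacency)."""
    return net.adjacency.sum(axis=1).astype(float)


def nodal_clustering(net: BinaryNetwork) -> np.ndarray:
    """C_X = 2 E_X / (D_X (D_X - 1)); 0 where degree < 2.

    E_X is the number of edges among X's neighbours, i.e. triangles
    through X, read off the diagonal of A^3.
    """
    a = net.adjacency.astype(np.int64)
    deg = a.sum(axis=1)
    triangles2 = np.einsum("ij,jk,ki->i", a, a, a)  # = 2 E_X per node
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles2 / denom, 0.0)
    return c.astype(float)


def mean_clustering(net: BinaryNetwork) -> float:
    """Arithmetic mean of C_X over all regions, zero-degree ones included."""
    return float(nodal_clustering(net).mean())


def betweenness_centrality(net: BinaryNetwork) -> np.ndarray:
    """Unnormalised geodesic betweenness, unordered pairs, endpoints excluded.

    Shortest-path counts accumulate along breadth-first predecessor trees
    (Brandes' algorithm, via networkx).
    """
    g = nx.from_numpy_array(net.adjacency)
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(net.n_regions)], dtype=float)


def local_efficiency(net: BinaryNetwork) -> np.ndarray:
    """Global efficiency of the subgraph induced on each node's neighbours.

    Distances are measured within the neighbour subgraph (X removed); the
    average runs over ordered neighbour pairs.  Nodes with < 2 neighbours
    score 0.
    """
    a = net.adjacency
    n = net.n_regions
    out = np.zeros(n, dtype=float)
    for x in range(n):
        nbrs = np.flatnonzero(a[x])
        m = nbrs.size
        if m < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        d = shortest_path(sub, method="D", unweighted=True, directed=False)
        off = ~np.eye(m, dtype=bool)
        inv = np.where(np.isfinite(d[off]), 1.0 / d[off], 0.0)
        out[x] = inv.sum() / (m * (m - 1))
    return out


def all_metrics(net: BinaryNetwork) -> tuple[GlobalMetrics, NodalMetrics]:
    """Everything in one call; the all-pairs BFS is shared between L and E_glob."""
    dist = shortest_path_lengths(net)
    l, e_glob, frac = _pathlength_stats(dist)
    nodal_c = nodal_clustering(net)
    glob = GlobalMetrics(
        L=l,
        E_glob=e_glob,
        C=float(nodal_c.mean()),
        n_regions=net.n_regions,
        connected_pair_fraction=frac,
    )
    nodal = NodalMetrics(
        degree=degree_centrality(net),
        clustering=nodal_c,
        betweenness=betweenness_centrality(net),
        local_efficiency=local_efficiency(net),
        region_labels=net.region_labels,
    )
    return glob, nodal
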