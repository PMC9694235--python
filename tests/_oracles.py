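"""Independent brute-force oracles used to pin down the implementations.

Everything here is written from first principles (BFS path enumeration,
iterative peeling, dense eigendecomposition, linear solves, explicit wavelet
basis vectors) and never calls the package's own code paths.
"""

from __future__ import annotations

from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# Haar wavelet: explicit basis-vector matrix

def haar_matrix(n: int, levels: int) -> tuple[np.ndarray, list[str]]:
    """Rows are the orthonormal Haar analysis vectors for d1..dL, aL.

    The level-l detail vector k is +2^{-l/2} on samples
    [k*2^l, k*2^l + 2^(l-1)) and -2^{-l/2} on the second half of its
    support; the level-L approximation vectors are +2^{-L/2} on their
    support.
    """
    rows = []
    names = []
    for lev in range(1, levels + 1):
        width = 1 << lev
        amp = width ** -0.5
        for k in range(n // width):
            v = np.zeros(n)
            v[k * width : k * width + width // 2] = amp
            v[k * width + width // 2 : (k + 1) * width] = -amp
            rows.append(v)
            names.append(f"d{lev}_{k}")
    width = 1 << levels
    amp = width ** -0.5
    for k in range(n // width):
        v = np.zeros(n)
        v[k * width : (k + 1) * width] = amp
        rows.append(v)
        names.append(f"a{levels}_{k}")
    return np.array(rows), names


# ---------------------------------------------------------------------------
# graph measures on a binary adjacency matrix

def betweenness_oracle(adj: np.ndarray) -> np.ndarray:
    """Unnormalized shortest-path betweenness by explicit BFS enumeration.

    For each unordered pair (s, t) every intermediate node v on a shortest
    path receives fractional credit sigma_sv * sigma_vt / sigma_st.
    """
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s, s] = 0
        sigma[s, s] = 1
        q = deque([s])
        while q:
            u = q.popleft()
            for v in np.nonzero(adj[u])[0]:
                if dist[s, v] == np.inf:
                    dist[s, v] = dist[s, u] + 1
                    q.append(v)
                if dist[s, v] == dist[s, u] + 1:
                    sigma[s, v] += sigma[s, u]
    btw = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]):
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    btw[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return btw


def core_number_oracle(adj: np.ndarray) -> np.ndarray:
    """k-core by iterative peeling of minimum-degree nodes."""
    n = adj.shape[0]
    alive = np.ones(n, bool)
    core = np.zeros(n, int)
    k = 0
    while alive.any():
        while True:
            deg = (adj[np.ix_(alive, alive)]).sum(axis=1)
            nodes = np.nonzero(alive)[0]
            low = nodes[deg <= k] if nodes.size else []
            if len(low) == 0:
                break
            for v in low:
                core[v] = k
                alive[v] = False
        k += 1
    return core


def subgraph_centrality_oracle(adj: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(adj)
    return (vecs ** 2 * np.exp(vals)[None, :]).sum(axis=1)


def eigenvector_centrality_oracle(adj: np.ndarray, iters: int = 5000) -> np.ndarray:
    """Power iteration on A + I (strict spectral dominance of the Perron
    eigenvalue on any graph with at least one edge)."""
    n = adj.shape[0]
    v = np.ones(n) / np.sqrt(n)
    m = adj + np.eye(n)
    for _ in range(iters):
        v = m @ v
        v /= np.linalg.norm(v)
    return np.abs(v)


def pagerank_oracle(adj: np.ndarray, alpha: float = 0.85) -> np.ndarray:
    """Closed-form solve of the PageRank linear system (no dangling nodes)."""
    n = adj.shape[0]
    deg = adj.sum(axis=1)
    assert (deg > 0).all(), "oracle assumes no dangling nodes"
    m = adj / deg[None, :]  # column-stochastic: m[i, j] = A_ij / deg_j
    p = np.linalg.solve(np.eye(n) - alpha * m, (1 - alpha) / n * np.ones(n))
    return p / p.sum()


def assortativity_oracle(adj: np.ndarray) -> float:
    """Pearson correlation of end-point degrees over directed edge list."""
    deg = adj.sum(axis=1)
    xs, ys = [], []
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    xs, ys = np.array(xs, float), np.array(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def connected_atlas_adjacencies(max_nodes: int = 6) -> list[np.ndarray]:
    """All connected graphs with 2..max_nodes nodes, up to isomorphism."""
    import networkx as nx

    out = []
    for g in nx.graph_atlas_g():
        n = g.number_of_nodes()
        if 2 <= n <= max_nodes and nx.is_connected(g):
            out.append(nx.to_numpy_array(g, nodelist=sorted(g.nodes)))
    return out
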