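"""ROI connectivity graphs and the ten graph-theoretic node/graph measures.

The connectivity graph is built from absolute Pearson correlation between ROI
time series and sparsified by proportional thresholding (keep the strongest
fraction ``density`` of off-diagonal weights).  Eight node-level measures
(degree, strength, diversity coefficient, betweenness, k-coreness, subgraph,
eigenvector and PageRank centrality) and two graph-level measures
(assortativity, small-worldness) are computed on the thresholded graph.

Binary vs weighted: strength and the diversity coefficient use the retained
weights; all other measures use the binary (masked) topology.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ConnectivityGraph",
    "GlobalMeasures",
    "GRAPH_FEATURE_NAMES",
    "connectivity_matrix",
    "threshold_graph",
    "local_graph_measures",
    "global_graph_measures",
]

#: The ten graph features in canonical output order.
GRAPH_FEATURE_NAMES: list[str] = [
    "degree",
    "node_strength",
    "diversity_coefficient",
    "betweenness_centrality",
    "k_coreness_centrality",
    "subgraph_centrality",
    "eigenvector_centrality",
    "pagerank_centrality",
    "assortativity",
    "small_worldness",
]


@dataclasses.dataclass(frozen=True)
class ConnectivityGraph:
    """Symmetric weighted graph with an optional binary retention mask."""

    weights: np.ndarray
    mask: np.ndarray | None = None
    density: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != w.shape or not np.array_equal(m, m.T):
                raise ValueError("mask must be symmetric and match weights")
            object.__setattr__(self, "mask", m)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def _require_mask(self) -> np.ndarray:
        if self.mask is None:
            raise ValueError("graph has no retention mask; call threshold_graph first")
        return self.mask

    def to_networkx(self, weighted: bool = False) -> nx.Graph:
        """Masked graph as networkx; binary topology, weights optional."""
        m = self._require_mask()
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        ii, jj = np.nonzero(np.triu(m, 1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            if weighted:
                g.add_edge(i, j, weight=float(self.weights[i, j]))
            else:
                g.add_edge(i, j)
        return g


def connectivity_matrix(roi_series_matrix: np.ndarray) -> ConnectivityGraph:
    """Absolute Pearson correlation between ROI series, zero diagonal."""
    x = np.asarray(roi_series_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a matrix with at least 2 ROI series")
    sd = x.std(axis=1)
    # relative tolerance: a numerically constant series has sd at rounding level
    flat = np.nonzero(sd <= 1e-12 * (np.abs(x).max(axis=1) + 1.0))[0]
    if flat.size:
        raise ValueError(f"constant time series for ROI index {int(flat[0])}")
    w = np.abs(np.corrcoef(x))
    np.fill_diagonal(w, 0.0)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)  # symmetrize away rounding
    return ConnectivityGraph(weights=w)


def threshold_graph(graph: ConnectivityGraph, density: float) -> ConnectivityGraph:
    """Proportional thresholding: keep the top-``density`` fraction of edges.

    Exactly ``round(density * n(n-1)/2)`` edges are retained; ties at the cut
    are broken deterministically in favour of the lexicographically smallest
    (i, j) pair.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    n = graph.n_nodes
    ii, jj = np.triu_indices(n, 1)
    order = sorted(
        range(ii.size),
        key=lambda k: (-graph.weights[ii[k], jj[k]], int(ii[k]), int(jj[k])),
    )
    n_keep = int(round(density * ii.size))
    mask = np.zeros((n, n), dtype=bool)
    for k in order[:n_keep]:
        mask[ii[k], jj[k]] = mask[jj[k], ii[k]] = True
    return ConnectivityGraph(weights=graph.weights, mask=mask, density=density)


# ---------------------------------------------------------------------------
# node-level measures

def _modules(graph: ConnectivityGraph) -> list[set[int]]:
    """Modules by greedy modularity maximization on the weighted masked graph.

    Output order is made deterministic by sorting modules on their smallest
    node index.
    """
    g = graph.to_networkx(weighted=True)
    if g.number_of_edges() == 0:
        return [set(g.nodes)]
    comms = nx.community.greedy_modularity_communities(g, weight="weight")
    return sorted((set(c) for c in comms), key=min)


def _diversity(graph: ConnectivityGraph, modules: Sequence[set[int]]) -> np.ndarray:
    """Normalized Shannon entropy of each node's strength across modules."""
    m = graph._require_mask()
    w = graph.weights * m
    n = graph.n_nodes
    n_mod = len(modules)
    out = np.zeros(n)
    if n_mod < 2:
        return out
    member = np.zeros((n_mod, n))
    for k, mod in enumerate(modules):
        member[k, sorted(mod)] = 1.0
    smod = member @ w  # strength of node j into module k -> (n_mod, n)
    tot = smod.sum(axis=0)
    for j in range(n):
        if tot[j] <= 0:
            continue
        p = smod[:, j] / tot[j]
        p = p[p > 0]
        out[j] = float(-(p * np.log(p)).sum() / np.log(n_mod))
    return out


def _eigenvector_centrality(adj: np.ndarray) -> np.ndarray:
    """Principal eigenvector of the binary adjacency, unit norm, non-negative."""
    if adj.sum() == 0:
        raise ValueError("eigenvector centrality undefined on a graph with no edges")
    vals, vecs = np.linalg.eigh(adj)
    v = vecs[:, -1]
    v = np.abs(v)
    return v / np.linalg.norm(v)


def local_graph_measures(graph: ConnectivityGraph, node: int | None = None) -> np.ndarray:
    """The eight node-level measures, as an ``n_nodes x 8`` array.

    Column order matches ``GRAPH_FEATURE_NAMES[:8]``.  With ``node`` given,
    returns that node's row.  Betweenness is the unnormalized shortest-path
    count (fractional credit for ties), computed within components on
    disconnected graphs; PageRank uses damping 0.85 with uniform teleport.
    """
    if graph.n_nodes < 2:
        raise ValueError("graph must have at least 2 nodes")
    m = graph._require_mask()
    g = graph.to_networkx(weighted=False)
    n = graph.n_nodes
    adj = m.astype(float)

    degree = adj.sum(axis=1)
    strength = (graph.weights * m).sum(axis=1)
    diversity = _diversity(graph, _modules(graph))
    btw_d = nx.betweenness_centrality(g, normalized=False)
    betweenness = np.array([btw_d[i] for i in range(n)])
    core_d = nx.core_number(g)
    coreness = np.array([core_d[i] for i in range(n)], dtype=float)
    sub_d = nx.subgraph_centrality(g)
    subgraph = np.array([sub_d[i] for i in range(n)])
    eigen = _eigenvector_centrality(adj)
    pr_d = nx.pagerank(g, alpha=0.85)
    pagerank = np.array([pr_d[i] for i in range(n)])

    out = np.column_stack(
        [degree, strength, diversity, betweenness, coreness, subgraph, eigen, pagerank]
    )
    return out if node is None else out[node]


# ---------------------------------------------------------------------------
# graph-level measures

@dataclasses.dataclass(frozen=True)
class GlobalMeasures:
    assortativity: float
    small_worldness: float
    flags: tuple[str, ...] = ()


def _clustering_and_path_length(g: nx.Graph) -> tuple[float, float]:
    c = nx.average_clustering(g)
    comp = max(nx.connected_components(g), key=len)
    if len(comp) < 2:
        return c, float("nan")
    sub = g.subgraph(comp)
    return c, nx.average_shortest_path_length(sub)


def _rewired_null(g: nx.Graph, rng_seed: int) -> nx.Graph:
    """Degree-preserving rewire: 10 swap attempts per edge, seeded.

    Graphs where no swap is feasible (e.g. complete graphs) are returned as
    they are, which is itself degree-preserving.
    """
    h = g.copy()
    n_attempts = 10 * h.number_of_edges()
    if h.number_of_nodes() < 4 or n_attempts == 0:
        return h
    try:
        nx.double_edge_swap(h, nswap=n_attempts, max_tries=n_attempts, seed=rng_seed)
    except nx.NetworkXException:
        pass  # ran out of tries; keep whatever swaps succeeded
    return h


def global_graph_measures(
    graph: ConnectivityGraph, n_rewires: int = 20, seed: int = 0
) -> GlobalMeasures:
    """Assortativity and small-worldness of the masked graph.

    Assortativity is the Pearson degree-degree correlation over edges; a
    degree-regular graph has no variance, so it is reported as 0 with a flag.
    Small-worldness is sigma = (C/C_rand) / (L/L_rand) against an ensemble of
    ``n_rewires`` seeded degree-preserving rewired graphs; a null ensemble
    with zero clustering yields +inf with a flag.
    """
    g = graph.to_networkx(weighted=False)
    if g.number_of_edges() == 0:
        raise ValueError("global measures need at least one edge")
    flags: list[str] = []

    degrees = [d for _, d in g.degree()]
    if len(set(degrees)) == 1:
        assort = 0.0
        flags.append("degenerate_assortativity")
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            assort = float(nx.degree_assortativity_coefficient(g))
        if not np.isfinite(assort):
            assort = 0.0
            flags.append("degenerate_assortativity")

    c, length = _clustering_and_path_length(g)
    seeds = np.random.SeedSequence(seed).generate_state(n_rewires)
    c_rand = []
    l_rand = []
    for s in seeds:
        c_r, l_r = _clustering_and_path_length(_rewired_null(g, int(s % (2**31))))
        c_rand.append(c_r)
        l_rand.append(l_r)
    c_null = float(np.mean(c_rand))
    l_null = float(np.nanmean(l_rand))
    if c_null == 0.0:
        sigma = float("inf")
        flags.append("zero_clustering_null")
    elif not np.isfinite(length) or not np.isfinite(l_null) or length == 0:
        sigma = float("nan")
        flags.append("degenerate_path_length")
    else:
        sigma = (c / c_null) / (length / l_null)
    return GlobalMeasures(assort, sigma, tuple(flags))
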