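"""Per-node topological scores on an undirected simple PPI graph.

Nine quantities are provided: degree (DC), betweenness (BC), eigenvector
(EC), subgraph (SC), local average connectivity (LAC), neighbourhood (NC)
and Laplacian (LC) centralities, and the two neighbourhood densities Den1
and Den2. Every function returns a plain ``{protein: float}`` map with
exactly one finite entry per node.

Conventions where the underlying definitions are ambiguous:

* BC is unnormalized, counts each unordered node pair once, excludes the
  endpoints, and gives disconnected pairs zero weight.
* EC is the principal adjacency eigenvector, non-negative, unit Euclidean
  norm; in a disconnected graph only the component with the largest
  adjacency eigenvalue carries mass, all other nodes score 0.
* NC terms whose denominator ``min(deg(v)-1, deg(u)-1)`` is zero contribute
  0 — a pendant edge supports no triangles.
* LC is evaluated through the degree-based closed form of the Laplacian
  energy, ``E_L(G) = sum(deg^2) + 2|E|``, which is exact; the spectral
  definition is equivalent and is retained as a test oracle
  (:func:`laplacian_energy_spectral`).
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import scipy.linalg

ScoreMap = dict[str, float]

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "subgraph_centrality",
    "lac",
    "nc",
    "laplacian_centrality",
    "laplacian_energy",
    "laplacian_energy_spectral",
    "den1",
    "den2",
]

# above this size betweenness goes through igraph's C implementation
_IGRAPH_MIN_NODES = 300


def degree_centrality(net: nx.Graph) -> ScoreMap:
    """DC(v) = deg(v)."""
    return {v: float(d) for v, d in net.degree()}


def betweenness_centrality(net: nx.Graph) -> ScoreMap:
    """Unnormalized shortest-path betweenness.

    BC(v) = sum over unordered pairs {s, t} (s, t != v) of
    sigma_st(v) / sigma_st; pairs with no connecting path contribute 0.
    """
    if net.number_of_nodes() >= _IGRAPH_MIN_NODES:
        try:
            return _betweenness_igraph(net)
        except ImportError:  # pragma: no cover - igraph is a hard dependency
            pass
    return {v: float(b) for v, b in nx.betweenness_centrality(net, normalized=False).items()}


def _betweenness_igraph(net: nx.Graph) -> ScoreMap:
    import igraph

    nodes = list(net.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.edges()]
    g = igraph.Graph(n=len(nodes), edges=edges, directed=False)
    values = g.betweenness(directed=False)
    return {v: float(values[i]) for v, i in index.items()}


def eigenvector_centrality(
    net: nx.Graph, tol: float = 1e-10, max_iter: int = 10_000
) -> ScoreMap:
    """Principal adjacency eigenvector, non-negative, unit Euclidean norm.

    Power iteration per connected component; the component with the largest
    adjacency eigenvalue (ties broken towards the component holding the
    lexicographically smallest node) carries the vector, all other nodes
    score exactly 0.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("eigenvector centrality is undefined on an empty network")
    best: tuple[float, str] | None = None
    best_vec: dict[str, float] = {}
    for comp in nx.connected_components(net):
        nodes = sorted(comp)
        lam, vec = _power_iteration(net.subgraph(comp), nodes, tol, max_iter)
        key = (lam, min(nodes))
        if best is None or lam > best[0] + tol or (abs(lam - best[0]) <= tol and key[1] < best[1]):
            best, best_vec = key, dict(zip(nodes, vec))
    scores = {v: 0.0 for v in net.nodes()}
    norm = math.sqrt(sum(x * x for x in best_vec.values()))
    if norm == 0.0:  # single isolated node / edgeless component won the tie
        # constant vector on the winning component, unit norm overall
        k = len(best_vec)
        best_vec = {v: 1.0 / math.sqrt(k) for v in best_vec}
        norm = 1.0
    for v, x in best_vec.items():
        scores[v] = x / norm
    return scores


def _power_iteration(
    sub: nx.Graph, nodes: list[str], tol: float, max_iter: int
) -> tuple[float, np.ndarray]:
    n = len(nodes)
    if sub.number_of_edges() == 0:
        return 0.0, np.zeros(n)
    adj = nx.to_numpy_array(sub, nodelist=nodes)
    x = np.full(n, 1.0 / math.sqrt(n))
    lam = 0.0
    # iterate with A + I: the shift breaks the +/-lambda symmetry of
    # bipartite components, where plain power iteration oscillates
    for _ in range(max_iter):
        y = adj @ x + x
        lam = float(np.linalg.norm(y))
        if lam == 0.0:
            return 0.0, np.zeros(n)
        y /= lam
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    x = np.abs(x)  # Perron vector is non-negative
    x /= np.linalg.norm(x)
    return lam - 1.0, x


def subgraph_centrality(net: nx.Graph) -> ScoreMap:
    """SC(v) = sum_k mu_k(v)/k!, the diagonal of exp(A).

    Dense matrix exponential up to 2000 nodes, symmetric eigendecomposition
    beyond; both evaluate the closed-walk series exactly.
    """
    nodes = list(net.nodes())
    if not nodes:
        return {}
    adj = nx.to_numpy_array(net, nodelist=nodes)
    if len(nodes) <= 2000:
        diag = np.diag(scipy.linalg.expm(adj))
    else:
        lam, vec = np.linalg.eigh(adj)
        diag = (vec**2) @ np.exp(lam)
    return {v: float(diag[i]) for i, v in enumerate(nodes)}


def lac(net: nx.Graph) -> ScoreMap:
    """Local average connectivity: mean degree of v's neighbours within
    the subgraph induced on the neighbourhood; 0 for isolated nodes."""
    scores: ScoreMap = {}
    adjacency = {v: set(net[v]) for v in net.nodes()}
    for v, neigh in adjacency.items():
        if not neigh:
            scores[v] = 0.0
            continue
        internal = sum(len(adjacency[u] & neigh) for u in neigh)
        scores[v] = internal / len(neigh)
    return scores


def nc(net: nx.Graph) -> ScoreMap:
    """Neighbourhood centrality: sum over edges (v,u) of the edge clustering
    coefficient z_{v,u} / min(deg(v)-1, deg(u)-1); degenerate terms are 0."""
    scores: ScoreMap = {}
    adjacency = {v: set(net[v]) for v in net.nodes()}
    degree = {v: len(a) for v, a in adjacency.items()}
    for v, neigh in adjacency.items():
        total = 0.0
        for u in neigh:
            denom = min(degree[v] - 1, degree[u] - 1)
            if denom > 0:
                total += len(adjacency[v] & adjacency[u]) / denom
        scores[v] = total
    return scores


def laplacian_energy(net: nx.Graph) -> float:
    """E_L(G) = sum of squared Laplacian eigenvalues = sum(deg^2) + 2|E|."""
    return float(sum(d * d for _, d in net.degree()) + 2 * net.number_of_edges())


def laplacian_energy_spectral(net: nx.Graph) -> float:
    """E_L(G) evaluated from the eigenvalues of L = X - W (test oracle)."""
    n = net.number_of_nodes()
    if n == 0:
        return 0.0
    lap = nx.laplacian_matrix(net).toarray().astype(float)
    eig = np.linalg.eigvalsh(lap)
    return float(np.sum(eig**2))


def laplacian_centrality(net: nx.Graph) -> ScoreMap:
    """LC(v) = (E_L(G) - E_L(G - v)) / E_L(G).

    Removing v cancels deg(v)^2, one unit of squared degree plus two edge
    units per incident edge, i.e. the energy drop is
    ``deg(v)^2 + deg(v) + 2 * sum of neighbour degrees``.
    """
    total = laplacian_energy(net)
    if total == 0.0:
        raise ValueError("Laplacian centrality is undefined on an edgeless network")
    degree = dict(net.degree())
    scores: ScoreMap = {}
    for v in net.nodes():
        d = degree[v]
        drop = d * d + d + 2 * sum(degree[u] for u in net[v])
        scores[v] = drop / total
    return scores


def _density_from_set(adjacency: dict[str, set[str]], members: set[str]) -> float:
    k = len(members)
    if k <= 1:
        return 0.0
    edges2 = sum(len(adjacency[u] & members) for u in members)  # counts both ends
    return edges2 / (k * (k - 1))


def den1(net: nx.Graph) -> ScoreMap:
    """Density of the subgraph induced on v and its neighbours; 0 when the
    induced node set has a single node."""
    adjacency = {v: set(net[v]) for v in net.nodes()}
    return {v: _density_from_set(adjacency, adjacency[v] | {v}) for v in adjacency}


def den2(net: nx.Graph) -> ScoreMap:
    """Density of the subgraph induced on v, its neighbours and the nodes at
    distance exactly 2 from v."""
    adjacency = {v: set(net[v]) for v in net.nodes()}
    scores: ScoreMap = {}
    for v, neigh in adjacency.items():
        ring2: set[str] = set()
        for u in neigh:
            ring2 |= adjacency[u]
        ring2 -= neigh
        ring2.discard(v)
        scores[v] = _density_from_set(adjacency, neigh | ring2 | {v})
    return scores
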