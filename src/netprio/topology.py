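"""The fourteen topological indices used as the raw per-gene feature set.

These mirror the node statistics exported by the Cytoscape ecosystem
(CytoNCA / NetworkAnalyzer): MNC, EPC, Bottleneck, raw and normalized
betweenness, closeness, degree, radiality, stress, average shortest-path
length, clustering coefficient, neighborhood connectivity, topological
coefficient, and number of undirected edges.  All distance-based indices
use unweighted shortest paths evaluated per connected component:
cross-component pairs are excluded rather than treated as infinitely far
apart, and degenerate cases (singleton components, degree < 2) yield 0.

Raw ``Betweenness`` sums fractions of geodesics over unordered pairs; the
normalized ``BetweennessCentrality`` twin equals raw betweenness times
2 / ((n-1)(n-2)) with n the size of the node's component (0 when n < 3).
``NumberOfUndirectedEdges`` equals ``Degree`` on a simple graph but is kept
as its own column for fidelity to the exported feature set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _sp_components

from .graph_io import GeneList, Graph

__all__ = [
    "CENTRALITY_COLUMNS",
    "centrality_table",
    "hub_intersection",
    "degree",
    "closeness",
    "avg_shortest_path_length",
    "radiality",
    "betweenness",
    "betweenness_centrality",
    "stress",
    "clustering_coefficient",
    "neighborhood_connectivity",
    "topological_coefficient",
    "mnc",
    "epc",
    "bottleneck",
]

#: Column order of the per-gene feature table.
CENTRALITY_COLUMNS = (
    "MNC",
    "EPC",
    "Bottleneck",
    "BetweennessCentrality",
    "ClosenessCentrality",
    "Degree",
    "Radiality",
    "Stress",
    "AverageShortestPathLength",
    "ClusteringCoefficient",
    "NeighborhoodConnectivity",
    "TopologicalCoefficient",
    "NumberOfUndirectedEdges",
    "Betweenness",
)


# ---------------------------------------------------------------------------
# Internal integer-indexed view
# ---------------------------------------------------------------------------

@dataclass
class _Indexed:
    nodes: list[str]                # lexicographic
    adj: list[np.ndarray]           # sorted neighbor indices per node
    edges: np.ndarray               # (m, 2) int array, u < v
    comp_label: np.ndarray          # component id per node
    comp_size: np.ndarray           # size per component id


def _index_graph(g: Graph) -> _Indexed:
    nodes = g.sorted_nodes()
    pos = {n: i for i, n in enumerate(nodes)}
    adj = [np.array(sorted(pos[w] for w in g.neighbors(n)), dtype=np.int64) for n in nodes]
    edges = np.array([(pos[u], pos[v]) for u, v in g.edges()], dtype=np.int64).reshape(-1, 2)
    n = len(nodes)
    label = np.full(n, -1, dtype=np.int64)
    sizes: list[int] = []
    for start in range(n):
        if label[start] >= 0:
            continue
        cid = len(sizes)
        stack = [start]
        label[start] = cid
        count = 1
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if label[w] < 0:
                    label[w] = cid
                    stack.append(int(w))
                    count += 1
        sizes.append(count)
    return _Indexed(nodes, adj, edges, label, np.array(sizes, dtype=np.int64))


def _bfs_dist_sigma(ix: _Indexed) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest-path distances and geodesic counts.

    Distances are +inf for unreachable pairs; sigma counts are 0 there and
    1 on the diagonal.
    """
    n = len(ix.nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        d = np.full(n, -1, dtype=np.int64)
        sig = np.zeros(n)
        d[s] = 0
        sig[s] = 1.0
        frontier = [s]
        while frontier:
            nxt: list[int] = []
            for u in frontier:
                du1 = d[u] + 1
                for w in ix.adj[u]:
                    if d[w] < 0:
                        d[w] = du1
                        nxt.append(int(w))
                    if d[w] == du1:
                        sig[w] += sig[u]
            frontier = nxt
        reached = d >= 0
        dist[s, reached] = d[reached]
        sigma[s] = sig
    return dist, sigma


def _betweenness_stress_all(dist: np.ndarray, sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw betweenness and stress for every node, by geodesic counting.

    A node v lies on a geodesic between s and t iff d(s,v)+d(v,t)=d(s,t);
    the number of such geodesics is sigma(s,v)*sigma(v,t) and the
    betweenness contribution is that count divided by sigma(s,t).  Sums run
    over unordered pairs s != t with v interior.
    """
    n = dist.shape[0]
    bet = np.zeros(n)
    stress = np.zeros(n)
    finite = np.isfinite(dist)
    np.fill_diagonal(finite, False)
    for v in range(n):
        through = dist[:, v][:, None] + dist[v, :][None, :]
        on = finite & (through == dist)
        on[v, :] = False
        on[:, v] = False
        if not on.any():
            continue
        paths = sigma[:, v][:, None] * sigma[v, :][None, :]
        paths = np.where(on, paths, 0.0)
        stress[v] = paths.sum() / 2.0
        frac = np.divide(paths, sigma, out=np.zeros_like(paths), where=on)
        bet[v] = frac.sum() / 2.0
    return bet, stress


def _bottleneck_all(ix: _Indexed, dist: np.ndarray) -> np.ndarray:
    """Bottleneck: for how many roots s does v's BFS-tree subtree exceed
    a quarter of the component?  Equal-distance parent choices are broken
    by lexicographically smallest parent symbol, giving deterministic trees.
    """
    n = len(ix.nodes)
    counts = np.zeros(n, dtype=np.int64)
    for s in range(n):
        d = dist[s]
        reach = np.isfinite(d)
        members = np.flatnonzero(reach)
        n_c = len(members)
        if n_c <= 1:
            continue
        parent = np.full(n, -1, dtype=np.int64)
        for w in members:
            if w == s:
                continue
            target = d[w] - 1
            for u in ix.adj[w]:        # adj sorted => first hit is smallest
                if d[u] == target:
                    parent[w] = u
                    break
        size = np.ones(n, dtype=np.int64)
        order = members[np.argsort(-d[members], kind="stable")]
        for w in order:
            if w != s:
                size[parent[w]] += size[w]
        quota = n_c / 4.0
        for v in members:
            if v != s and size[v] > quota:
                counts[v] += 1
    return counts


def _epc_all(ix: _Indexed, retain_p: float, iterations: int, seed: int) -> np.ndarray:
    """Monte-Carlo edge-percolated component size for every node."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not 0.0 <= retain_p <= 1.0:
        raise ValueError("retain_p must lie in [0, 1]")
    n = len(ix.nodes)
    m = len(ix.edges)
    rng = np.random.default_rng(seed)
    acc = np.zeros(n)
    for _ in range(iterations):
        if m:
            keep = rng.random(m) < retain_p
            kept = ix.edges[keep]
        else:
            kept = ix.edges
        if len(kept):
            mat = coo_matrix(
                (np.ones(len(kept)), (kept[:, 0], kept[:, 1])), shape=(n, n)
            )
            _, labels = _sp_components(mat, directed=False)
            sizes = np.bincount(labels)
            acc += sizes[labels]
        else:
            acc += 1.0
    return acc / iterations


# ---------------------------------------------------------------------------
# Local indices
# ---------------------------------------------------------------------------

def _clustering_all(ix: _Indexed) -> np.ndarray:
    n = len(ix.nodes)
    adjsets = [set(map(int, a)) for a in ix.adj]
    out = np.zeros(n)
    for v in range(n):
        k = len(ix.adj[v])
        if k < 2:
            continue
        nbset = adjsets[v]
        links = sum(len(adjsets[int(u)] & nbset) for u in ix.adj[v]) // 2
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def _neighborhood_connectivity_all(ix: _Indexed) -> np.ndarray:
    deg = np.array([len(a) for a in ix.adj], dtype=float)
    out = np.zeros(len(ix.nodes))
    for v in range(len(ix.nodes)):
        if len(ix.adj[v]):
            out[v] = deg[ix.adj[v]].mean()
    return out


def _topological_coefficient_all(ix: _Indexed) -> np.ndarray:
    n = len(ix.nodes)
    adjsets = [set(map(int, a)) for a in ix.adj]
    out = np.zeros(n)
    for v in range(n):
        k = len(ix.adj[v])
        if k < 1:
            continue
        shared: dict[int, int] = {}
        for u in ix.adj[v]:
            for w in adjsets[int(u)]:
                if w != v:
                    shared[w] = shared.get(w, 0) + 1
        if not shared:
            continue
        total = sum(c + (1 if w in adjsets[v] else 0) for w, c in shared.items())
        out[v] = total / (len(shared) * k)
    return out


def _mnc_all(ix: _Indexed) -> np.ndarray:
    n = len(ix.nodes)
    adjsets = [set(map(int, a)) for a in ix.adj]
    out = np.zeros(n, dtype=np.int64)
    for v in range(n):
        nb = adjsets[v]
        if not nb:
            continue
        remaining = set(nb)
        best = 0
        while remaining:
            start = remaining.pop()
            comp = 1
            stack = [start]
            while stack:
                u = stack.pop()
                for w in adjsets[u]:
                    if w in remaining:
                        remaining.discard(w)
                        comp += 1
                        stack.append(w)
            best = max(best, comp)
        out[v] = best
    return out


# ---------------------------------------------------------------------------
# Assembled table
# ---------------------------------------------------------------------------

def centrality_table(
    g: Graph,
    *,
    epc_retain_p: float = 0.5,
    epc_iterations: int = 1000,
    seed: int = 42,
) -> pd.DataFrame:
    """Compute all 14 topological indices for every node of ``g``.

    Returns a DataFrame indexed by gene symbol (lexicographic order) with
    the columns of :data:`CENTRALITY_COLUMNS`.  Deterministic given the
    seed (only EPC is stochastic).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot compute centralities on an empty graph")
    ix = _index_graph(g)
    n = len(ix.nodes)
    dist, sigma = _bfs_dist_sigma(ix)
    finite = np.isfinite(dist)
    np.fill_diagonal(finite, False)

    deg = np.array([len(a) for a in ix.adj], dtype=float)
    reach = finite.sum(axis=1).astype(float)              # r = reachable, self excluded
    sum_d = np.where(finite, dist, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        clo = np.where(sum_d > 0, reach / sum_d, 0.0)
        aspl = np.where(reach > 0, sum_d / np.maximum(reach, 1.0), 0.0)

    comp_of = ix.comp_label
    comp_sizes = ix.comp_size
    diam = np.zeros(len(comp_sizes))
    for cid in range(len(comp_sizes)):
        members = np.flatnonzero(comp_of == cid)
        if len(members) > 1:
            sub = dist[np.ix_(members, members)]
            diam[cid] = sub[np.isfinite(sub)].max()
    n_c = comp_sizes[comp_of].astype(float)
    rad = np.zeros(n)
    nontrivial = n_c > 1
    if nontrivial.any():
        bonus = (diam[comp_of] + 1.0) * reach
        rad[nontrivial] = (bonus - sum_d)[nontrivial] / (n_c[nontrivial] - 1.0)

    bet, stress_v = _betweenness_stress_all(dist, sigma)
    denom = (n_c - 1.0) * (n_c - 2.0)
    bet_norm = np.where(n_c >= 3, 2.0 * bet / np.where(denom > 0, denom, 1.0), 0.0)

    table = pd.DataFrame(
        {
            "MNC": _mnc_all(ix),
            "EPC": _epc_all(ix, epc_retain_p, epc_iterations, seed),
            "Bottleneck": _bottleneck_all(ix, dist),
            "BetweennessCentrality": bet_norm,
            "ClosenessCentrality": clo,
            "Degree": deg,
            "Radiality": rad,
            "Stress": stress_v,
            "AverageShortestPathLength": aspl,
            "ClusteringCoefficient": _clustering_all(ix),
            "NeighborhoodConnectivity": _neighborhood_connectivity_all(ix),
            "TopologicalCoefficient": _topological_coefficient_all(ix),
            "NumberOfUndirectedEdges": deg,
            "Betweenness": bet,
        },
        index=pd.Index(ix.nodes, name="gene"),
    )
    return table[list(CENTRALITY_COLUMNS)]


# ---------------------------------------------------------------------------
# Per-node convenience functions
# ---------------------------------------------------------------------------

def _node_index(g: Graph, v: str) -> tuple[_Indexed, int]:
    if v not in g:
        raise KeyError(f"unknown node {v!r}")
    ix = _index_graph(g)
    return ix, ix.nodes.index(v)


def degree(g: Graph, v: str) -> int:
    """Number of distinct neighbors of ``v``."""
    if v not in g:
        raise KeyError(f"unknown node {v!r}")
    return g.degree(v)


def closeness(g: Graph, v: str) -> float:
    """Reachable-node count divided by the sum of distances (0 if isolated)."""
    ix, i = _node_index(g, v)
    dist, _ = _bfs_dist_sigma(ix)
    d = dist[i]
    mask = np.isfinite(d)
    mask[i] = False
    total = d[mask].sum()
    return float(mask.sum() / total) if total > 0 else 0.0


def avg_shortest_path_length(g: Graph, v: str) -> float:
    """Mean distance to reachable nodes (0 when none are reachable)."""
    ix, i = _node_index(g, v)
    dist, _ = _bfs_dist_sigma(ix)
    d = dist[i]
    mask = np.isfinite(d)
    mask[i] = False
    return float(d[mask].mean()) if mask.any() else 0.0


def radiality(g: Graph, v: str) -> float:
    """Sum of (component diameter + 1 - d(v, w)) over reachable w, divided
    by component size minus one; 0 for singleton components."""
    return float(centrality_table(g, epc_iterations=1).loc[v, "Radiality"])


def betweenness(g: Graph, v: str) -> float:
    """Raw betweenness: sum over unordered pairs of geodesic fractions."""
    ix, i = _node_index(g, v)
    dist, sigma = _bfs_dist_sigma(ix)
    bet, _ = _betweenness_stress_all(dist, sigma)
    return float(bet[i])


def betweenness_centrality(g: Graph, v: str) -> float:
    """Normalized betweenness: raw value times 2/((n-1)(n-2)), n = component size."""
    return float(centrality_table(g, epc_iterations=1).loc[v, "BetweennessCentrality"])


def stress(g: Graph, v: str) -> float:
    """Number of geodesics (unordered pairs) passing through interior ``v``."""
    ix, i = _node_index(g, v)
    dist, sigma = _bfs_dist_sigma(ix)
    _, st = _betweenness_stress_all(dist, sigma)
    return float(st[i])


def clustering_coefficient(g: Graph, v: str) -> float:
    ix, i = _node_index(g, v)
    return float(_clustering_all(ix)[i])


def neighborhood_connectivity(g: Graph, v: str) -> float:
    ix, i = _node_index(g, v)
    return float(_neighborhood_connectivity_all(ix)[i])


def topological_coefficient(g: Graph, v: str) -> float:
    ix, i = _node_index(g, v)
    return float(_topological_coefficient_all(ix)[i])


def mnc(g: Graph, v: str) -> int:
    """Size of the largest connected component among ``v``'s neighbors."""
    ix, i = _node_index(g, v)
    return int(_mnc_all(ix)[i])


def epc(
    g: Graph,
    v: str,
    retain_p: float = 0.5,
    iterations: int = 1000,
    seed: int = 42,
) -> float:
    """Monte-Carlo mean size of ``v``'s component under random edge retention."""
    ix, i = _node_index(g, v)
    return float(_epc_all(ix, retain_p, iterations, seed)[i])


def bottleneck(g: Graph, v: str) -> int:
    ix, i = _node_index(g, v)
    dist, _ = _bfs_dist_sigma(ix)
    return int(_bottleneck_all(ix, dist)[i])


# ---------------------------------------------------------------------------
# Hub intersection
# ---------------------------------------------------------------------------

def hub_intersection(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = ("MNC", "EPC", "Bottleneck", "Betweenness"),
    top_k: int = 22,
) -> GeneList:
    """Genes in the top-``top_k`` of every listed metric simultaneously.

    Top-k selection uses a closed ranking: every gene tied with the k-th
    largest value is included, so the result is independent of symbol
    order and nested as ``top_k`` grows.  The intersection is returned in
    order of mean fractional rank across the metrics (ties by symbol).
    """
    missing = [m for m in metrics if m not in table.columns]
    if missing:
        raise ValueError(f"metrics not in table: {missing}")
    n = len(table)
    if not 1 <= top_k <= n:
        raise ValueError(f"top_k must lie in [1, {n}], got {top_k}")
    selected: frozenset[str] | None = None
    for m in metrics:
        col = table[m]
        cutoff = col.nlargest(top_k).iloc[-1]
        chosen = frozenset(col.index[col >= cutoff])
        selected = chosen if selected is None else selected & chosen
    assert selected is not None
    ranks = table[list(metrics)].rank(ascending=False, method="average")
    mean_rank = ranks.mean(axis=1)
    ordered = sorted(selected, key=lambda gene: (mean_rank[gene], gene))
    return GeneList.from_iterable("hubs", ordered)
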