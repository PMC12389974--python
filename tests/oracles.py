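"""Brute-force reference implementations used to validate the topology code.

Everything here is computed by explicit enumeration on top of networkx
(all-geodesic path listing, induced-subgraph scans, parent-pointer tree
walks) and is deliberately independent of the production algorithms in
``netprio.topology``.  Only suitable for small graphs.
"""

from __future__ import annotations

import itertools

import networkx as nx

from netprio.graph_io import Graph


def to_nx(g: Graph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(g.sorted_nodes())
    G.add_edges_from(g.edges())
    return G


def from_nx(G: nx.Graph) -> Graph:
    g = Graph(nodes=[str(n) for n in G.nodes])
    for u, v in G.edges:
        if str(u) != str(v):
            g.add_edge(str(u), str(v))
    return g


def oracle_table(g: Graph) -> dict[str, dict[str, float]]:
    """All 13 deterministic indices for every node, by explicit enumeration."""
    G = to_nx(g)
    nodes = sorted(G.nodes)
    dist = {s: nx.single_source_shortest_path_length(G, s) for s in nodes}
    comps = [sorted(c) for c in nx.connected_components(G)]
    comp_of = {v: tuple(c) for c in comps for v in c}

    # enumerate every geodesic of every connected unordered pair once
    bet = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        paths = list(nx.all_shortest_paths(G, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            hits = sum(1 for p in paths if v in p[1:-1])
            if hits:
                stress[v] += hits
                bet[v] += hits / len(paths)

    out: dict[str, dict[str, float]] = {}
    for v in nodes:
        comp = comp_of[v]
        n_c = len(comp)
        d = dist[v]
        reach = [w for w in comp if w != v]
        sum_d = sum(d[w] for w in reach)
        diam = max(
            (dist[a][b] for a in comp for b in comp if b in dist[a]), default=0
        )
        k = G.degree(v)
        nb = set(G.neighbors(v))

        # clustering by counting neighbor-neighbor edges
        e_n = sum(1 for a, b in itertools.combinations(sorted(nb), 2) if G.has_edge(a, b))
        clust = 2 * e_n / (k * (k - 1)) if k >= 2 else 0.0

        # topological coefficient: partners share at least one neighbor
        partners = {}
        for w in nodes:
            if w == v:
                continue
            shared = len(nb & set(G.neighbors(w)))
            if shared:
                partners[w] = shared + (1 if G.has_edge(v, w) else 0)
        tc = sum(partners.values()) / (len(partners) * k) if partners and k else 0.0

        mnc_val = (
            max((len(c) for c in nx.connected_components(G.subgraph(nb))), default=0)
            if nb
            else 0
        )

        out[v] = {
            "MNC": float(mnc_val),
            "Bottleneck": float(_oracle_bottleneck(G, dist, comp_of, v)),
            "BetweennessCentrality": (
                2.0 * bet[v] / ((n_c - 1) * (n_c - 2)) if n_c >= 3 else 0.0
            ),
            "ClosenessCentrality": len(reach) / sum_d if sum_d else 0.0,
            "Degree": float(k),
            "Radiality": (
                sum(diam + 1 - d[w] for w in reach) / (n_c - 1) if n_c > 1 else 0.0
            ),
            "Stress": float(stress[v]),
            "AverageShortestPathLength": sum_d / len(reach) if reach else 0.0,
            "ClusteringCoefficient": clust,
            "NeighborhoodConnectivity": (
                sum(G.degree(w) for w in nb) / k if k else 0.0
            ),
            "TopologicalCoefficient": tc,
            "NumberOfUndirectedEdges": float(k),
            "Betweenness": bet[v],
        }
    return out


def _oracle_bottleneck(G: nx.Graph, dist, comp_of, v: str) -> int:
    """Count roots whose lexicographic BFS tree hangs > n_c/4 nodes at v,
    with subtree sizes obtained by walking parent pointers upward."""
    comp = comp_of[v]
    n_c = len(comp)
    count = 0
    for s in comp:
        if s == v:
            continue
        d = dist[s]
        parent = {}
        for w in comp:
            if w == s:
                continue
            preds = sorted(u for u in G.neighbors(w) if d.get(u) == d[w] - 1)
            parent[w] = preds[0]
        size = {w: 0 for w in comp}
        for w in comp:
            node = w
            size[node] += 1
            while node != s:
                node = parent[node]
                size[node] += 1
        if size[v] > n_c / 4:
            count += 1
    return count


def oracle_betweenness_nx(g: Graph) -> dict[str, float]:
    """Second, fully independent cross-check via networkx's Brandes code."""
    return nx.betweenness_centrality(to_nx(g), normalized=False)
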