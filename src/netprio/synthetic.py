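"""Seeded synthetic inputs with known ground truth.

Real compound-target networks come from live database snapshots that
cannot be redistributed, so every pipeline stage is exercised on
generated data instead: a preferential-attachment (scale-free-like) PPI
stand-in with a handful of planted super-hub genes, gene lists with a
controlled overlap, Gaussian feature clouds with planted clusters and
outliers, and GMT collections with planted enriched sets.  Filler genes
are named ``G000001...`` and planted entities ``HUB1...`` /
``PLANTED_SET_1...`` so ground truth is grep-able.  Every generator is a
pure function of its parameters and seed.

Preferential attachment is used (rather than uniformly random edges)
because degree heterogeneity is precisely what the composite score
exploits; no claim of biological realism is made beyond that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph_io import GeneList, Graph

__all__ = [
    "SyntheticTruth",
    "generate_ppi",
    "generate_target_sets",
    "generate_feature_clouds",
    "generate_gmt",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted by a generator; regenerable from params + seed."""

    seed: int
    params: dict
    hub_genes: tuple[str, ...] = ()
    outlier_rows: tuple[int, ...] = ()
    cluster_labels: tuple[int, ...] = ()
    enriched_sets: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "params": self.params,
            "hub_genes": list(self.hub_genes),
            "outlier_rows": list(self.outlier_rows),
            "cluster_labels": list(self.cluster_labels),
            "enriched_sets": list(self.enriched_sets),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _filler_names(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def generate_ppi(
    n_nodes: int = 364,
    edges_per_new_node: int = 2,
    n_hubs: int = 5,
    hub_extra_degree: int = 40,
    seed: int = 42,
) -> tuple[Graph, SyntheticTruth]:
    """Connected scale-free-like network with planted super-hub genes.

    Growth by preferential attachment: the first two nodes share an edge
    and each subsequent node attaches to ``edges_per_new_node`` distinct
    existing nodes chosen proportionally to degree, giving
    1 + m * (n_nodes - 2) base edges.  ``n_hubs`` nodes drawn uniformly
    from the later three quarters of the growth order are renamed
    ``HUB1..`` and receive extra neighbors chosen degree-weighted without
    replacement (hub partners are enriched for the dense network core, as
    in real interactomes, which also gives hubs the large connected
    neighborhoods that MNC rewards); hub j gets
    ``(j + 1) * hub_extra_degree`` of them, so even the weakest planted
    hub sits well above the natural preferential-attachment maximum.
    The staggering mirrors
    the heavy-tailed top of real interaction networks, where the apex
    genes' degrees are themselves spread out rather than piled at one
    value, and makes each planted hub individually extreme in feature
    space.  Because the hubs are meant to be unambiguous ground truth,
    any hub still at or below the highest filler degree is topped up
    with further random attachments until it strictly exceeds it, so
    planted hubs always occupy the top of the degree ranking.
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    m = edges_per_new_node
    if not 1 <= m < n_nodes:
        raise ValueError("edges_per_new_node must lie in [1, n_nodes)")
    if n_hubs < 0 or n_hubs > n_nodes // 4:
        raise ValueError("n_hubs must lie in [0, n_nodes/4]")
    rng = np.random.default_rng(seed)

    adj: list[set[int]] = [set() for _ in range(n_nodes)]
    endpoints: list[int] = [0, 1]  # degree-weighted sampling pool
    adj[0].add(1)
    adj[1].add(0)
    for new in range(2, n_nodes):
        targets: set[int] = set()
        want = min(m, new)
        while len(targets) < want:
            t = int(endpoints[rng.integers(len(endpoints))])
            targets.add(t)
        for t in targets:
            adj[new].add(t)
            adj[t].add(new)
            endpoints.extend((new, t))

    hub_ids = sorted(
        rng.choice(np.arange(n_nodes // 4, n_nodes), size=n_hubs, replace=False)
    ) if n_hubs else []
    hub_set = set(int(h) for h in hub_ids)
    for j, h in enumerate(hub_ids, start=1):
        h = int(h)
        candidates = [
            v for v in range(n_nodes) if v != h and v not in adj[h] and v not in hub_set
        ]
        weights = np.array([len(adj[v]) for v in candidates], dtype=float)
        weights = np.maximum(weights, 1.0)
        extra = rng.choice(
            len(candidates),
            size=min((j + 1) * hub_extra_degree, len(candidates)),
            replace=False,
            p=weights / weights.sum(),
        )
        for idx in extra:
            v = candidates[int(idx)]
            adj[h].add(v)
            adj[v].add(h)
    for _ in range(50):
        if not hub_set:
            break
        max_filler = max(len(adj[v]) for v in range(n_nodes) if v not in hub_set)
        deficient = [h for h in hub_ids if len(adj[int(h)]) <= max_filler]
        if not deficient:
            break
        for h in deficient:
            h = int(h)
            pool = [
                v for v in range(n_nodes)
                if v != h and v not in adj[h] and v not in hub_set
            ]
            rng.shuffle(pool)
            while len(adj[h]) <= max_filler and pool:
                v = pool.pop()
                adj[h].add(v)
                adj[v].add(h)

    names = _filler_names(n_nodes)
    for rank, h in enumerate(hub_ids, start=1):
        names[int(h)] = f"HUB{rank}"
    g = Graph()
    for u in range(n_nodes):
        for v in adj[u]:
            if u < v:
                g.add_edge(names[u], names[v])
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_nodes": n_nodes,
            "edges_per_new_node": m,
            "n_hubs": n_hubs,
            "hub_extra_degree": hub_extra_degree,
        },
        hub_genes=tuple(names[int(h)] for h in hub_ids),
    )
    return g, truth


def generate_target_sets(
    universe_N: int,
    K: int,
    M: int,
    overlap_x: int,
    seed: int = 42,
) -> tuple[GeneList, GeneList]:
    """Two gene lists of sizes K and M with an exact intersection of size x,
    drawn from a universe of ``universe_N`` filler symbols."""
    if overlap_x > min(K, M):
        raise ValueError("overlap_x cannot exceed min(K, M)")
    if K + M - overlap_x > universe_N:
        raise ValueError("universe too small for the requested cardinalities")
    rng = np.random.default_rng(seed)
    universe = np.array(_filler_names(universe_N))
    perm = rng.permutation(universe_N)
    shared = universe[perm[:overlap_x]]
    only_a = universe[perm[overlap_x : K]]
    only_b = universe[perm[K : K + M - overlap_x]]
    a = np.concatenate([shared, only_a])
    b = np.concatenate([shared, only_b])
    rng.shuffle(a)
    rng.shuffle(b)
    return (
        GeneList.from_iterable("targets_a", a),
        GeneList.from_iterable("targets_b", b),
    )


def generate_feature_clouds(
    n_per_cluster: int = 50,
    n_clusters: int = 3,
    separation: float = 10.0,
    n_outliers: int = 0,
    outlier_distance: float = 10.0,
    dim: int = 2,
    seed: int = 42,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Unit-variance Gaussian clusters plus optional planted outlier rows.

    Cluster centroids are pairwise ``separation`` standard deviations
    apart (exactly so whenever ``n_clusters - 1 <= dim``, as the vertices
    of a randomly rotated regular simplex; approximately otherwise).
    Outlier rows are placed
    ``outlier_distance`` SDs from the global centroid mean in random
    directions and appended after the cluster rows.
    """
    if n_clusters < 1 or n_per_cluster < 1:
        raise ValueError("need at least one cluster with at least one point")
    rng = np.random.default_rng(seed)
    if n_clusters == 1:
        centroids = np.zeros((1, dim))
    elif n_clusters - 1 <= dim:
        # regular simplex with side = separation, randomly rotated into R^dim
        m = n_clusters
        simplex = np.eye(m) - 1.0 / m
        u, s, _ = np.linalg.svd(simplex)
        coords = u[:, : m - 1] * s[: m - 1]          # pairwise distance sqrt(2)
        coords *= separation / np.sqrt(2.0)
        q, _ = np.linalg.qr(rng.normal(size=(dim, m - 1)))
        centroids = coords @ q[:, : m - 1].T
    else:
        centroids = rng.normal(size=(n_clusters, dim))
        d = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        centroids *= separation / d.min()
    rows = []
    labels = []
    for c in range(n_clusters):
        rows.append(centroids[c] + rng.normal(size=(n_per_cluster, dim)))
        labels.extend([c] * n_per_cluster)
    X = np.vstack(rows)
    center = centroids.mean(axis=0)
    outlier_rows = []
    if n_outliers:
        dirs = rng.normal(size=(n_outliers, dim))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        outs = center + outlier_distance * dirs
        start = len(X)
        X = np.vstack([X, outs])
        outlier_rows = list(range(start, start + n_outliers))
        labels.extend([-1] * n_outliers)
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_per_cluster": n_per_cluster,
            "n_clusters": n_clusters,
            "separation": separation,
            "n_outliers": n_outliers,
            "outlier_distance": outlier_distance,
            "dim": dim,
        },
        outlier_rows=tuple(outlier_rows),
        cluster_labels=tuple(labels),
    )
    return X, truth


def generate_gmt(
    universe: GeneList,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 50),
    enriched_query: GeneList | None = None,
    n_enriched: int = 3,
    seed: int = 42,
    path: str | Path | None = None,
) -> tuple[dict[str, tuple[str, ...]], SyntheticTruth]:
    """GMT collection with ``n_enriched`` sets planted to overlap a query.

    Planted sets draw 80% of their members from ``enriched_query`` and the
    rest uniformly from the remaining universe; filler sets are uniform
    over the whole universe.  If ``path`` is given the collection is also
    written in GMT format.
    """
    from .stats import write_gmt

    if enriched_query is None:
        n_enriched = 0
    if n_enriched > n_sets:
        raise ValueError("n_enriched cannot exceed n_sets")
    lo, hi = set_size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError("set_size_range must satisfy 1 <= lo <= hi <= |universe|")
    rng = np.random.default_rng(seed)
    uni = np.array(list(universe))
    query = np.array(sorted(enriched_query.as_set)) if enriched_query else np.array([])
    non_query = np.array(sorted(universe.as_set - set(query)))
    sets: dict[str, tuple[str, ...]] = {}
    enriched_names = []
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        if i <= n_enriched:
            name = f"PLANTED_SET_{i}"
            n_from_query = min(int(round(0.8 * size)), len(query))
            members = list(rng.choice(query, size=n_from_query, replace=False))
            rest = size - n_from_query
            if rest:
                members += list(rng.choice(non_query, size=min(rest, len(non_query)),
                                           replace=False))
            enriched_names.append(name)
        else:
            name = f"SET_{i:03d}"
            members = list(rng.choice(uni, size=size, replace=False))
        sets[name] = tuple(dict.fromkeys(members))
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_sets": n_sets,
            "set_size_range": list(set_size_range),
            "n_enriched": n_enriched,
            "universe_size": len(universe),
        },
        enriched_sets=tuple(enriched_names),
    )
    if path is not None:
        write_gmt(sets, path)
    return sets, truth
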