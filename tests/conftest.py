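import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from netprio.graph_io import Graph


def path_graph(n: int) -> Graph:
    names = [chr(ord("A") + i) for i in range(n)]
    return Graph(zip(names, names[1:]))


def star_graph(n_leaves: int) -> Graph:
    return Graph(("C0", f"L{i}") for i in range(1, n_leaves + 1))


def cycle_graph(n: int) -> Graph:
    names = [f"N{i}" for i in range(n)]
    return Graph(zip(names, names[1:] + names[:1]))


def complete_graph(n: int) -> Graph:
    import itertools

    names = [f"N{i}" for i in range(n)]
    return Graph(itertools.combinations(names, 2))


@pytest.fixture
def p3() -> Graph:
    return path_graph(3)


@pytest.fixture
def triangle() -> Graph:
    return complete_graph(3)


@pytest.fixture
def random_graphs():
    """A suite of seeded Erdos-Renyi graphs of varying size and density."""
    import networkx as nx

    from oracles import from_nx

    graphs = []
    seed = 0
    for n in (4, 6, 9, 12, 18, 25):
        for p in (0.15, 0.3, 0.6):
            for _ in range(3):
                seed += 1
                G = nx.gnp_random_graph(n, p, seed=seed)
                G = nx.relabel_nodes(G, {i: f"N{i:02d}" for i in G.nodes})
                if G.number_of_edges() == 0:
                    continue
                G.remove_nodes_from(list(nx.isolates(G)))
                graphs.append(from_nx(G))
    return graphs
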