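"""Graph data model plus readers/writers for networks and gene lists.

The pipeline operates on undirected, unweighted, simple graphs whose nodes
are gene symbols.  Networks arrive either as STRING-style TSV exports
(node pair plus a combined confidence score) or as plain two-column edge
lists; gene sets arrive as one-symbol-per-line text files.  All readers
apply the same cleaning rules: symbols are upper-cased, self-loops are
dropped, duplicate pairs (in either orientation) are collapsed, and nodes
left without any edge are removed unless explicitly kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "Graph",
    "GeneList",
    "FormatError",
    "EmptyGraphError",
    "read_string_tsv",
    "read_edge_list",
    "read_gene_list",
    "write_gene_list",
    "write_table",
]


class FormatError(ValueError):
    """An input file does not follow the expected layout."""


class EmptyGraphError(ValueError):
    """Filtering left no usable network."""


def normalize_symbol(symbol: object) -> str:
    """Upper-case and strip a gene symbol; empty symbols are rejected."""
    s = str(symbol).strip().upper()
    if not s:
        raise FormatError("empty gene symbol")
    return s


class Graph:
    """Undirected simple graph over gene symbols.

    Invariants: no self-loops, no duplicate edges, symmetric adjacency,
    and every edge endpoint is a registered node.  Iteration orders
    (nodes, edges, components) are lexicographic so that downstream
    computations are deterministic.
    """

    __slots__ = ("_adj",)

    def __init__(self, edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()):
        self._adj: dict[str, set[str]] = {}
        for n in nodes:
            self.add_node(n)
        for u, v in edges:
            self.add_edge(u, v)

    # -- construction -------------------------------------------------
    def add_node(self, n: str) -> None:
        n = normalize_symbol(n)
        self._adj.setdefault(n, set())

    def add_edge(self, u: str, v: str) -> None:
        u, v = normalize_symbol(u), normalize_symbol(v)
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        self._adj.setdefault(u, set()).add(v)
        self._adj.setdefault(v, set()).add(u)

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._adj)

    def sorted_nodes(self) -> list[str]:
        return sorted(self._adj)

    def neighbors(self, v: str) -> frozenset[str]:
        return frozenset(self._adj[v])

    def degree(self, v: str) -> int:
        return len(self._adj[v])

    def has_node(self, v: str) -> bool:
        return v in self._adj

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._adj and v in self._adj[u]

    def number_of_nodes(self) -> int:
        return len(self._adj)

    def number_of_edges(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    def edges(self) -> Iterator[tuple[str, str]]:
        """Yield edges as sorted pairs, in lexicographic order."""
        for u in self.sorted_nodes():
            for v in sorted(self._adj[u]):
                if u < v:
                    yield (u, v)

    def __contains__(self, v: str) -> bool:
        return v in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self._adj == other._adj

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Graph(n={self.number_of_nodes()}, m={self.number_of_edges()})"

    def connected_components(self) -> list[frozenset[str]]:
        """Components ordered by their lexicographically smallest member."""
        seen: set[str] = set()
        comps: list[frozenset[str]] = []
        for start in self.sorted_nodes():
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for w in self._adj[u]:
                    if w not in comp:
                        comp.add(w)
                        stack.append(w)
            seen |= comp
            comps.append(frozenset(comp))
        return comps

    def subgraph(self, nodes: Iterable[str]) -> "Graph":
        keep = {normalize_symbol(n) for n in nodes}
        g = Graph()
        for n in keep:
            if n in self._adj:
                g.add_node(n)
        for u, v in self.edges():
            if u in keep and v in keep:
                g.add_edge(u, v)
        return g

    def copy(self) -> "Graph":
        g = Graph()
        g._adj = {u: set(nb) for u, nb in self._adj.items()}
        return g


@dataclass(frozen=True)
class GeneList:
    """Named, ordered, deduplicated collection of gene symbols."""

    name: str
    symbols: tuple[str, ...]

    @classmethod
    def from_iterable(cls, name: str, symbols: Iterable[object]) -> "GeneList":
        seen: dict[str, None] = {}
        for s in symbols:
            seen.setdefault(normalize_symbol(s), None)
        return cls(name=name, symbols=tuple(seen))

    @property
    def as_set(self) -> frozenset[str]:
        return frozenset(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.as_set


# ---------------------------------------------------------------------------
# Network readers
# ---------------------------------------------------------------------------

_NODE_COLUMN_PAIRS = [("protein1", "protein2"), ("node1", "node2")]
_SCORE_COLUMNS = ["combined_score", "score"]


def _clean_edges(
    pairs: Iterable[tuple[str, str]],
    all_nodes: set[str],
    drop_isolated: bool,
) -> Graph:
    g = Graph()
    for u, v in pairs:
        if u == v:
            continue
        g.add_edge(u, v)
    if not drop_isolated:
        for n in all_nodes:
            g.add_node(n)
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("no nodes remain after filtering")
    return g


def read_string_tsv(
    path: str | Path,
    min_score: float = 0.4,
    *,
    drop_isolated: bool = True,
) -> Graph:
    """Read a STRING-style TSV export, keeping edges at or above ``min_score``.

    The threshold is expressed on the 0-1 confidence scale; files carrying
    integer scores on the native 0-1000 scale are rescaled before the
    comparison.  Self-loops are dropped, duplicate pairs collapsed and
    (by default) nodes left without any passing edge are removed.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score must lie in [0, 1], got {min_score}")
    try:
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 3:
            df = pd.read_csv(path, sep=r"\s+")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc

    colmap = {c.strip().lstrip("#").lower(): c for c in df.columns}
    node_cols = None
    for a, b in _NODE_COLUMN_PAIRS:
        if a in colmap and b in colmap:
            node_cols = (colmap[a], colmap[b])
            break
    score_col = next((colmap[c] for c in _SCORE_COLUMNS if c in colmap), None)
    if node_cols is None or score_col is None:
        raise FormatError(
            f"{path}: expected node columns protein1/protein2 or node1/node2 "
            f"and a combined_score/score column; found {list(df.columns)}"
        )

    scores = pd.to_numeric(df[score_col], errors="coerce")
    if scores.isna().any():
        raise FormatError(f"{path}: non-numeric values in {score_col!r}")
    if (scores > 1.0).any():  # native STRING 0-1000 integer scale
        scores = scores / 1000.0

    u = df[node_cols[0]].map(normalize_symbol)
    v = df[node_cols[1]].map(normalize_symbol)
    all_nodes = set(u) | set(v)
    keep = scores >= min_score
    pairs = list(zip(u[keep], v[keep]))
    return _clean_edges(pairs, all_nodes, drop_isolated)


def read_edge_list(path: str | Path, *, drop_isolated: bool = True) -> Graph:
    """Read a two-column whitespace-separated edge list.

    Lines starting with ``#`` and blank lines are ignored.  Cleaning rules
    match :func:`read_string_tsv` minus the score filter.
    """
    pairs: list[tuple[str, str]] = []
    all_nodes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
                )
            u, v = (normalize_symbol(f) for f in fields)
            all_nodes.update((u, v))
            pairs.append((u, v))
    return _clean_edges(pairs, all_nodes, drop_isolated)


# ---------------------------------------------------------------------------
# Gene lists and tables
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list (CRLF tolerated, order kept)."""
    path = Path(path)
    if name is None:
        name = path.stem
    with open(path, encoding="utf-8") as fh:
        symbols = [line.strip() for line in fh if line.strip()]
    if not symbols:
        warnings.warn(f"{path}: empty gene list", stacklevel=2)
    return GeneList.from_iterable(name, symbols)


def write_gene_list(genes: GeneList | Iterable[str], path: str | Path) -> None:
    symbols = list(genes)
    with open(path, "w", encoding="utf-8") as fh:
        for s in symbols:
            fh.write(f"{s}\n")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-gene table as CSV with a header and deterministic rows.

    Rows are ordered by ``composite_rank`` when that column exists,
    otherwise lexicographically by gene.
    """
    df = table.copy()
    if df.index.name in (None, "") and "gene" not in df.columns:
        df.index.name = "gene"
    if "gene" not in df.columns:
        df = df.reset_index()
    if "composite_rank" in df.columns:
        df = df.sort_values(["composite_rank", "gene"], kind="mergesort")
    else:
        df = df.sort_values("gene", kind="mergesort")
    df.to_csv(path, index=False)
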