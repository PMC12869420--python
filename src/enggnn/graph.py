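"""Feature graphs and adjacency algebra.

A :class:`FeatureGraph` is a node-labelled graph over a fixed, ordered feature
space.  Node identity is positional: index ``i`` always refers to
``node_labels[i]``, and every adjacency matrix produced here is aligned to that
ordering.  Undirected edges are stored canonically as ``(min, max)`` pairs and
expand symmetrically when converted to adjacency form.  Isolated nodes are
permitted and preserved — a feature with no known interactions still occupies a
row/column of the adjacency matrix (and therefore still reaches its own hidden
unit once self-loops are added).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FeatureGraph",
    "AdjacencyMatrix",
    "to_adjacency",
    "augment_with_self_loops",
    "union_graphs",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary adjacency matrix ``A`` (or ``Ã = A + I`` when ``self_loops``).

    ``values`` is a ``p × p`` array with entries in ``{0, 1}``.  For a directed
    graph, ``values[u, v] = 1`` means the edge ``u → v`` (row = source); for an
    undirected graph the matrix is symmetric.
    """

    values: np.ndarray
    self_loops: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.values)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency matrix must be square, got shape {a.shape}")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if self.self_loops and not (np.diag(a) == 1).all():
            raise ValueError("self_loops=True requires a unit diagonal")
        object.__setattr__(self, "values", a.astype(np.float64))

    @property
    def p(self) -> int:
        return self.values.shape[0]


class FeatureGraph:
    """Node-labelled feature graph, directed or undirected.

    Parameters
    ----------
    node_labels
        Ordered feature identifiers; length defines ``p``.
    edges
        ``(source, target)`` index pairs in ``[0, p)``.  For undirected graphs
        each pair is canonicalised to ``(min, max)``.
    directed
        Edge orientation flag.
    """

    def __init__(
        self,
        node_labels: Sequence[str],
        edges: Iterable[tuple[int, int]] = (),
        directed: bool = False,
    ) -> None:
        self.node_labels: list[str] = list(node_labels)
        self.directed = bool(directed)
        p = len(self.node_labels)
        canon: set[tuple[int, int]] = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if not (0 <= u < p and 0 <= v < p):
                raise ValueError(f"edge ({u}, {v}) outside node range [0, {p})")
            if not self.directed and u > v:
                u, v = v, u
            canon.add((u, v))
        self.edges: frozenset[tuple[int, int]] = frozenset(canon)

    @property
    def p(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureGraph):
            return NotImplemented
        return (
            self.node_labels == other.node_labels
            and self.directed == other.directed
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        kind = "directed" if self.directed else "undirected"
        return f"FeatureGraph(p={self.p}, edges={self.n_edges}, {kind})"

    def degrees(self) -> np.ndarray:
        """Node degrees (total degree for directed graphs)."""
        deg = np.zeros(self.p, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            if v != u:
                deg[v] += 1
        return deg


def to_adjacency(graph: FeatureGraph) -> AdjacencyMatrix:
    """Binary adjacency matrix of ``graph`` (no self-loops).

    Entry ``(u, v)`` is 1 iff the edge ``u → v`` exists; undirected edges set
    both ``(u, v)`` and ``(v, u)``.
    """
    a = np.zeros((graph.p, graph.p))
    for u, v in graph.edges:
        a[u, v] = 1.0
        if not graph.directed:
            a[v, u] = 1.0
    return AdjacencyMatrix(a, self_loops=False)


def augment_with_self_loops(adj: AdjacencyMatrix) -> AdjacencyMatrix:
    """Return ``Ã = A + I`` clipped to ``{0, 1}``.

    Off-diagonal entries are unchanged; pre-existing self-loops do not produce
    entries of 2.
    """
    a = np.minimum(adj.values + np.eye(adj.p), 1.0)
    return AdjacencyMatrix(a, self_loops=True)


def union_graphs(graphs: Sequence[FeatureGraph]) -> FeatureGraph:
    """Edge-set union of graphs sharing one label space and directedness."""
    if len(graphs) == 0:
        raise ValueError("cannot union an empty list of graphs")
    first = graphs[0]
    for g in graphs[1:]:
        if g.node_labels != first.node_labels:
            raise ValueError("graphs have mismatched node label spaces")
        if g.directed != first.directed:
            raise ValueError("graphs have mismatched directedness")
    edges: set[tuple[int, int]] = set()
    for g in graphs:
        edges |= set(g.edges)
    return FeatureGraph(first.node_labels, edges, directed=first.directed)


def read_edge_list(
    path,
    node_labels: Sequence[str],
    directed: bool = False,
    on_unknown: str = "error",
) -> FeatureGraph:
    """Read a two-column ``source target`` edge list into a FeatureGraph.

    Lines are whitespace- or tab-delimited; ``#``-prefixed lines are comments.
    Labels absent from ``node_labels`` either raise (``on_unknown='error'``) or
    drop the edge (``on_unknown='skip'``).
    """
    if on_unknown not in ("error", "skip"):
        raise ValueError("on_unknown must be 'error' or 'skip'")
    index = {lab: i for i, lab in enumerate(node_labels)}
    edges: list[tuple[int, int]] = []
    skipped: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            src, dst = parts[0], parts[1]
            if src not in index or dst not in index:
                if on_unknown == "error":
                    raise ValueError(
                        f"{path}:{lineno}: unknown feature label in edge {src!r} -> {dst!r}"
                    )
                skipped.append(line)
                continue
            edges.append((index[src], index[dst]))
    return FeatureGraph(node_labels, edges, directed=directed)


def write_edge_list(graph: FeatureGraph, path) -> None:
    """Write ``graph`` as a two-column labelled edge list (tab-delimited)."""
    with open(path, "w") as fh:
        fh.write(f"# directed={graph.directed}\n")
        for u, v in sorted(graph.edges):
            fh.write(f"{graph.node_labels[u]}\t{graph.node_labels[v]}\n")
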