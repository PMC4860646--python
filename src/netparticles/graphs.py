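"""Graph and partition data model with edge-list, GML and partition-file I/O.

A :class:`Graph` is a simple undirected graph stored as a sparse adjacency
matrix over a dense internal node index ``0..N-1``; original node labels are
preserved for output.  The complement ("absent links") matrix
``R_ij = 1 - A_ij - delta_ij`` is never materialized densely — consumers work
with ``A`` and subtract its contribution analytically.

A :class:`Partition` maps each node to a community label; comparisons between
partitions are invariant under relabeling (see :mod:`netparticles.metrics`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import networkx as nx
import numpy as np
from scipy import sparse


class GraphFormatError(ValueError):
    """Raised for malformed or unsupported graph input."""


@dataclass(frozen=True)
class Graph:
    """Simple undirected graph with a dense internal node index.

    Parameters
    ----------
    adjacency
        Symmetric ``N x N`` binary CSR matrix with zero diagonal.
    node_labels
        Original node identifiers, position ``i`` holding the label of
        internal node ``i``.
    """

    adjacency: sparse.csr_matrix
    node_labels: tuple[Hashable, ...]

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape[0] != a.shape[1]:
            raise GraphFormatError("adjacency must be square")
        if a.shape[0] != len(self.node_labels):
            raise GraphFormatError("label count does not match adjacency size")
        if a.diagonal().any():
            raise GraphFormatError("self-loops are not allowed")
        if (a != a.T).nnz != 0:
            raise GraphFormatError("adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Per-node link count ``k_i``."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Edge set over internal indices, each pair ordered ``(min, max)``."""
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        return {(int(i), int(j)) for i, j in zip(coo.row, coo.col)}

    @property
    def edge_labels(self) -> set[frozenset]:
        """Edge set over original node labels (index-order independent)."""
        labs = self.node_labels
        return {frozenset((labs[i], labs[j])) for i, j in self.edges}

    def index_of(self, label: Hashable) -> int:
        return self.node_labels.index(label)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Hashable, Hashable]],
        nodes: Iterable[Hashable] | None = None,
    ) -> "Graph":
        """Build a graph from an iterable of unordered node pairs.

        Duplicate and reversed-duplicate pairs collapse to one edge.
        ``nodes`` may list extra (possibly isolated) nodes and fixes the
        label order; otherwise labels appear in first-seen order.
        """
        labels: list[Hashable] = list(nodes) if nodes is not None else []
        index: dict[Hashable, int] = {lab: i for i, lab in enumerate(labels)}
        if len(index) != len(labels):
            raise GraphFormatError("duplicate node label")

        pairs: set[tuple[int, int]] = set()
        for u, v in edges:
            if u == v:
                raise GraphFormatError(f"self-loop on node {u!r}")
            for w in (u, v):
                if w not in index:
                    index[w] = len(labels)
                    labels.append(w)
            i, j = index[u], index[v]
            pairs.add((min(i, j), max(i, j)))

        n = len(labels)
        if pairs:
            rows, cols = np.array(sorted(pairs)).T
            data = np.ones(len(pairs), dtype=np.int8)
            a = sparse.coo_matrix((data, (rows, cols)), shape=(n, n))
            a = (a + a.T).tocsr()
        else:
            a = sparse.csr_matrix((n, n), dtype=np.int8)
        return cls(adjacency=a, node_labels=tuple(labels))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        labs = self.node_labels
        g.add_edges_from((labs[i], labs[j]) for i, j in self.edges)
        return g


@dataclass(frozen=True)
class Partition:
    """Node -> community-label map ``y_i``."""

    labels: dict[Hashable, int] = field(default_factory=dict)

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    @property
    def nodes(self) -> set[Hashable]:
        return set(self.labels)

    def as_array(self, node_order: Iterable[Hashable]) -> np.ndarray:
        """Label vector in the given node order (e.g. a Graph's labels)."""
        return np.array([self.labels[n] for n in node_order], dtype=np.int64)

    def community_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    @classmethod
    def from_array(cls, labels: np.ndarray, node_order: Iterable[Hashable]) -> "Partition":
        return cls({n: int(c) for n, c in zip(node_order, labels)})


def load_edge_list(path: str | Path) -> Graph:
    """Load a whitespace-separated edge list; ``#`` starts a comment.

    Duplicate lines and reversed duplicates collapse to one edge.  Node
    tokens that parse as integers become integer labels so that files
    written with numeric ids round-trip.
    """
    edges: list[tuple[Hashable, Hashable]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected two node tokens, got {len(tokens)}"
                )
            u, v = (_coerce_token(t) for t in tokens)
            if u == v:
                raise GraphFormatError(f"{path}:{lineno}: self-loop on node {u!r}")
            edges.append((u, v))
    return Graph.from_edges(edges)


def _coerce_token(token: str) -> Hashable:
    try:
        return int(token)
    except ValueError:
        return token


def load_gml(path: str | Path) -> tuple[Graph, Partition | None]:
    """Load a GML file, returning the graph and a ground-truth partition
    when every node carries a ``value`` or ``community`` attribute."""
    try:
        g = nx.read_gml(path, label="id")
    except Exception as exc:  # networkx raises several parse-error types
        raise GraphFormatError(f"cannot parse GML file {path}: {exc}") from exc
    if g.is_directed():
        raise GraphFormatError(f"{path}: directed graphs are not supported")
    if g.is_multigraph():
        g = nx.Graph(g)
    loops = list(nx.selfloop_edges(g))
    if loops:
        raise GraphFormatError(f"{path}: self-loop on node {loops[0][0]!r}")
    for _, _, d in g.edges(data=True):
        if "weight" in d and d["weight"] not in (1, 1.0):
            warnings.warn("weighted edges are binarized", stacklevel=2)
            break

    nodes = list(g.nodes())
    graph = Graph.from_edges(g.edges(), nodes=nodes)

    partition: Partition | None = None
    for attr in ("value", "community"):
        values = nx.get_node_attributes(g, attr)
        if len(values) == len(nodes):
            partition = Partition({n: int(values[n]) for n in nodes})
            break
    return graph, partition


def save_partition(p: Partition, path: str | Path) -> None:
    """Write a partition as tab-separated ``node-id  community-id`` lines."""
    with open(path, "w") as fh:
        for node in sorted(p.labels, key=str):
            fh.write(f"{node}\t{p.labels[node]}\n")


def load_partition(path: str | Path) -> Partition:
    """Read a two-column partition file; duplicate node ids are an error."""
    labels: dict[Hashable, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if len(tokens) != 2:
                raise GraphFormatError(f"{path}:{lineno}: expected 'node<TAB>community'")
            node = _coerce_token(tokens[0])
            if node in labels:
                raise GraphFormatError(f"{path}:{lineno}: duplicate node id {node!r}")
            labels[node] = int(tokens[1])
    return Partition(labels)
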