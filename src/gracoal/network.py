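"""Undirected simple networks over string node labels.

The :class:`Network` is the universal input of the package: node labels are
kept in sorted order so that every downstream matrix, ranking and output file
is bit-reproducible.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import networkx as nx

__all__ = ["Network"]


class Network:
    """An undirected simple graph with deterministic (sorted) node order.

    Parameters
    ----------
    edges
        Iterable of 2-tuples of node labels. Self-loops and duplicate edges
        are rejected: cleaning of raw input files is the job of the readers
        in :mod:`gracoal.io`, not of the container.
    nodes
        Optional additional node labels (isolated nodes are allowed).
    """

    __slots__ = ("nodes", "edges", "_index", "_adj_bits", "_adj_sets")

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
    ) -> None:
        edge_set: set[tuple[str, str]] = set()
        node_set: set[str] = set(nodes)
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop at node {u!r}: network must be simple")
            key = (u, v) if u < v else (v, u)
            if key in edge_set:
                raise ValueError(f"duplicate edge {key!r}: network must be simple")
            edge_set.add(key)
            node_set.add(u)
            node_set.add(v)
        self.nodes: tuple[str, ...] = tuple(sorted(node_set))
        self.edges: tuple[tuple[str, str], ...] = tuple(sorted(edge_set))
        self._index = {u: i for i, u in enumerate(self.nodes)}
        n = len(self.nodes)
        adj_bits = [0] * n
        adj_sets: list[set[int]] = [set() for _ in range(n)]
        for u, v in self.edges:
            i, j = self._index[u], self._index[v]
            adj_bits[i] |= 1 << j
            adj_bits[j] |= 1 << i
            adj_sets[i].add(j)
            adj_sets[j].add(i)
        self._adj_bits = adj_bits
        self._adj_sets = adj_sets

    # -- basic queries ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)

    def index(self, label: str) -> int:
        return self._index[label]

    def has_edge(self, u: str, v: str) -> bool:
        iu = self._index.get(u)
        iv = self._index.get(v)
        if iu is None or iv is None:
            return False
        return iv in self._adj_sets[iu]

    def degree(self, u: str) -> int:
        return len(self._adj_sets[self._index[u]])

    def degrees(self) -> list[int]:
        """Degree of every node, in node order."""
        return [len(s) for s in self._adj_sets]

    def neighbors(self, u: str) -> tuple[str, ...]:
        return tuple(self.nodes[i] for i in sorted(self._adj_sets[self._index[u]]))

    # -- index-level access for the counting/embedding kernels -----------

    def adjacency_bits(self) -> list[int]:
        """Per-node neighbour bitmask (node order); internal fast path."""
        return list(self._adj_bits)

    def adjacency_sets(self) -> list[set[int]]:
        return [set(s) for s in self._adj_sets]

    # -- derived networks -------------------------------------------------

    def subgraph(self, keep: Iterable[str]) -> "Network":
        keep_set = set(keep)
        unknown = keep_set - set(self.nodes)
        if unknown:
            raise KeyError(f"nodes not in network: {sorted(unknown)[:5]}")
        edges = [(u, v) for u, v in self.edges if u in keep_set and v in keep_set]
        return Network(edges, nodes=keep_set)

    def connected_components(self) -> list[tuple[str, ...]]:
        """Components sorted by (size desc, smallest label) — deterministic."""
        g = self.to_networkx()
        comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: (-len(c), c[0]))
        return comps

    def largest_component(self) -> "Network":
        comps = self.connected_components()
        if not comps:
            return self
        return self.subgraph(comps[0])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        return cls(((str(u), str(v)) for u, v in g.edges()), nodes=(str(u) for u in g.nodes()))

    @classmethod
    def from_integer_edges(cls, edges: Sequence[tuple[int, int]], n_nodes: int, prefix: str = "n") -> "Network":
        """Build a labelled network from integer edges, zero-padding labels
        so that sorted label order equals integer order."""
        width = max(1, len(str(max(n_nodes - 1, 0))))
        lab = [f"{prefix}{i:0{width}d}" for i in range(n_nodes)]
        return cls(((lab[i], lab[j]) for i, j in edges), nodes=lab)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.nodes, self.edges))

    def __repr__(self) -> str:
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"
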