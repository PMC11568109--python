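"""Exact enumeration of 2-4-node graphlets (G0-G8), orbits and graphlet adjacency.

A *graphlet* is a small connected non-isomorphic induced subgraph. The nine
graphlets on 2-4 nodes, in the standard numbering, are::

    G0  edge            G3  4-path          G6  triangle+pendant (paw)
    G1  3-path          G4  3-star (claw)   G7  diamond
    G2  triangle        G5  4-cycle         G8  complete K4

Node positions within a graphlet fall into 15 automorphism orbits (orbit 0 =
end of an edge, ... orbit 14 = node of K4). For every node u and graphlet Gi
we count t_u(Gi), the number of induced occurrences of Gi touching u, and for
every node pair (u, v) the co-occurrence count c_uv(Gi): the number of
occurrences of Gi touching u and v simultaneously.

The *graphlet adjacency matrix* generalizes the ordinary adjacency matrix:

    A_Gi(u, v) = c_uv(Gi) / theta_Gi     (u != v; zero diagonal)

with theta_Gi = (number of nodes of Gi) - 1, so that each row sums to
t_u(Gi). A_G0 is exactly the binary adjacency matrix. The symmetrically
normalized form divides entry (u, v) by sqrt(t_u * t_v).

Enumeration is exhaustive and exact: connected induced subgraphs are grown
node-by-node from each anchor node with an exclusive-neighbourhood rule, so
every connected 2-4-node subset is visited exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network

__all__ = [
    "THETA",
    "GRAPHLET_SIZES",
    "ORBIT_PARENT",
    "GraphletCounts",
    "GraphletAdjacency",
    "count_graphlets",
    "count_node_orbits",
    "triangle_pair_counts",
    "graphlet_adjacency",
    "normalize_adjacency",
]

#: scaling constant theta_Gi = (#nodes of Gi) - 1, for G0..G8
THETA: tuple[int, ...] = (1, 2, 2, 3, 3, 3, 3, 3, 3)

#: number of nodes of each graphlet G0..G8
GRAPHLET_SIZES: tuple[int, ...] = (2, 3, 3, 4, 4, 4, 4, 4, 4)

#: parent graphlet of each of the 15 orbits
ORBIT_PARENT: tuple[int, ...] = (0, 1, 1, 2, 3, 3, 4, 4, 5, 6, 6, 6, 7, 7, 8)

# Within each graphlet the orbit of a node is determined by its induced
# degree; _ORBIT_OF[gi][deg] gives the orbit index (-1 = impossible).
_ORBIT_OF: tuple[tuple[int, ...], ...] = (
    (-1, 0, -1, -1),   # G0: deg 1 -> orbit 0
    (-1, 1, 2, -1),    # G1: ends 1, middle 2
    (-1, -1, 3, -1),   # G2: all deg 2 -> 3
    (-1, 4, 5, -1),    # G3: ends 4, middle 5
    (-1, 6, -1, 7),    # G4: leaves 6, hub 7
    (-1, -1, 8, -1),   # G5: all deg 2 -> 8
    (-1, 9, 10, 11),   # G6: pendant 9, far triangle 10, attachment 11
    (-1, -1, 12, 13),  # G7: rim 12, hinge 13
    (-1, -1, -1, 14),  # G8: all deg 3 -> 14
)


@dataclass(frozen=True)
class GraphletCounts:
    """Exact graphlet statistics of a network.

    Attributes
    ----------
    nodes
        Node labels in network (sorted) order; all arrays use this order.
    node_counts
        ``(n, 9)`` integer array, ``node_counts[u, i]`` = t_u(Gi).
    orbit_counts
        ``(n, 15)`` integer array of per-orbit touch counts.
    pair_counts
        Nine dicts mapping index pairs ``(i, j)`` with ``i < j`` to
        c_uv(Gi); absent key means zero. ``None`` if pairs were skipped.
    """

    nodes: tuple[str, ...]
    node_counts: np.ndarray
    orbit_counts: np.ndarray
    pair_counts: tuple[dict[tuple[int, int], int], ...] | None = field(repr=False, default=None)

    def pair_count(self, graphlet_index: int, u: str, v: str) -> int:
        """c_uv(Gi) for labelled nodes u, v."""
        if self.pair_counts is None:
            raise ValueError("pair counts were not computed")
        idx = {lab: k for k, lab in enumerate(self.nodes)}
        i, j = idx[u], idx[v]
        if i == j:
            return 0
        if i > j:
            i, j = j, i
        return self.pair_counts[graphlet_index].get((i, j), 0)

    def graphlet_totals(self) -> np.ndarray:
        """Number of occurrences of each graphlet in the whole network."""
        sizes = np.asarray(GRAPHLET_SIZES)
        return self.node_counts.sum(axis=0) // sizes


@dataclass(frozen=True)
class GraphletAdjacency:
    """Graphlet adjacency matrix A_Gi (optionally symmetrically normalized)."""

    graphlet_index: int
    nodes: tuple[str, ...]
    matrix: np.ndarray
    degree_diag: np.ndarray  # t_u(Gi) per node
    normalized: bool = False


def _classify4(e: int, dmax: int) -> int:
    """Graphlet index of a connected 4-node induced subgraph from its edge
    count e and maximum degree."""
    if e == 3:
        return 4 if dmax == 3 else 3
    if e == 4:
        return 6 if dmax == 3 else 5
    if e == 5:
        return 7
    return 8


def _enumerate(adj: list[int], n: int, include_pairs: bool):
    """Core kernel: one pass over all connected induced 2-4-node subsets.

    Subsets are grown from each anchor v using only nodes with index > v and
    an exclusive-neighbour extension rule, so each subset is produced once.
    """
    t = np.zeros((n, 9), dtype=np.int64)
    orb = np.zeros((n, 15), dtype=np.int64)
    pairs: tuple[dict, ...] | None = tuple({} for _ in range(9)) if include_pairs else None
    full = (1 << n) - 1
    orbit_of = _ORBIT_OF

    for v in range(n):
        bv = 1 << v
        mask_gt = full ^ ((bv << 1) - 1)
        adj_v = adj[v]
        e1 = adj_v & mask_gt
        while e1:
            bw = e1 & -e1
            e1 ^= bw
            w = bw.bit_length() - 1
            adj_w = adj[w]
            # ---- size 2: G0 ----
            t[v, 0] += 1
            t[w, 0] += 1
            orb[v, 0] += 1
            orb[w, 0] += 1
            if pairs is not None:
                key = (v, w)
                d0 = pairs[0]
                d0[key] = d0.get(key, 0) + 1
            S2 = bv | bw
            # exclusive-neighbour rule: nodes joining via w must not already
            # neighbour the subset {v}, else they were (or will be) reachable
            # from v directly and the subset would be produced twice
            e2 = e1 | (adj_w & mask_gt & ~(adj_v | bv))
            nbr2 = adj_v | adj_w | S2
            while e2:
                bx = e2 & -e2
                e2 ^= bx
                x = bx.bit_length() - 1
                adj_x = adj[x]
                S3 = S2 | bx
                dv = (adj_v & S3).bit_count()
                dw = (adj_w & S3).bit_count()
                dx = (adj_x & S3).bit_count()
                # ---- size 3: G1 (path) or G2 (triangle) ----
                if dv + dw + dx == 4:
                    gi = 1
                else:
                    gi = 2
                t[v, gi] += 1
                t[w, gi] += 1
                t[x, gi] += 1
                orb[v, orbit_of[gi][dv]] += 1
                orb[w, orbit_of[gi][dw]] += 1
                orb[x, orbit_of[gi][dx]] += 1
                if pairs is not None:
                    dgi = pairs[gi]
                    for a, b in ((v, w), (v, x) if v < x else (x, v), (w, x) if w < x else (x, w)):
                        dgi[(a, b)] = dgi.get((a, b), 0) + 1
                e3 = e2 | (adj_x & mask_gt & ~nbr2)
                while e3:
                    by = e3 & -e3
                    e3 ^= by
                    y = by.bit_length() - 1
                    adj_y = adj[y]
                    S4 = S3 | by
                    d1 = (adj_v & S4).bit_count()
                    d2 = (adj_w & S4).bit_count()
                    d3 = (adj_x & S4).bit_count()
                    d4 = (adj_y & S4).bit_count()
                    s = d1 + d2 + d3 + d4
                    m = d1
                    if d2 > m:
                        m = d2
                    if d3 > m:
                        m = d3
                    if d4 > m:
                        m = d4
                    gi = _classify4(s >> 1, m)
                    t[v, gi] += 1
                    t[w, gi] += 1
                    t[x, gi] += 1
                    t[y, gi] += 1
                    ogi = orbit_of[gi]
                    orb[v, ogi[d1]] += 1
                    orb[w, ogi[d2]] += 1
                    orb[x, ogi[d3]] += 1
                    orb[y, ogi[d4]] += 1
                    if pairs is not None:
                        dgi = pairs[gi]
                        quad = sorted((v, w, x, y))
                        a0, a1, a2, a3 = quad
                        for key in (
                            (a0, a1), (a0, a2), (a0, a3),
                            (a1, a2), (a1, a3), (a2, a3),
                        ):
                            dgi[key] = dgi.get(key, 0) + 1
    return t, orb, pairs


def count_graphlets(network: Network, include_pairs: bool = True) -> GraphletCounts:
    """Exhaustively count all induced 2-4-node graphlets of a network.

    Returns per-node graphlet touch counts t_u(Gi), per-node orbit counts
    and (unless ``include_pairs=False``) the symmetric pair co-occurrence
    counts c_uv(Gi). Counting is exact.

    Raises
    ------
    ValueError
        If the network has no nodes.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot count graphlets of an empty network")
    adj = network.adjacency_bits()
    t, orb, pairs = _enumerate(adj, network.n_nodes, include_pairs)
    return GraphletCounts(
        nodes=network.nodes,
        node_counts=t,
        orbit_counts=orb,
        pair_counts=pairs,
    )


def count_node_orbits(network: Network) -> GraphletCounts:
    """Node and orbit counts only (pair co-occurrences skipped).

    Identical to :func:`count_graphlets` with ``include_pairs=False``; the
    lighter form used by the graphlet-correlation machinery, where only
    orbit count columns are needed.
    """
    return count_graphlets(network, include_pairs=False)


def triangle_pair_counts(network: Network) -> dict[tuple[str, str], int]:
    """c_uv(G2) for every adjacent pair, computed via common neighbours.

    Two nodes co-occur on a triangle iff they are adjacent and share a
    neighbour; the count equals the size of the shared neighbourhood. Pairs
    not listed have zero triangle co-occurrence. Direct route used by the
    paralog analysis, where only G2 pairs are needed.
    """
    adj = network.adjacency_bits()
    out: dict[tuple[str, str], int] = {}
    nodes = network.nodes
    for u, v in network.edges:
        i, j = network.index(u), network.index(v)
        c = (adj[i] & adj[j]).bit_count()
        if c:
            out[(u, v)] = c
    return out


def graphlet_adjacency(counts: GraphletCounts, graphlet_index: int) -> GraphletAdjacency:
    """Build the (unnormalized) graphlet adjacency matrix A_Gi.

    Entry (u, v) = c_uv(Gi) / theta_Gi with theta_Gi = |V(Gi)| - 1; the
    diagonal is zero and each row sums to t_u(Gi).
    """
    if not 0 <= graphlet_index <= 8:
        raise ValueError(f"graphlet_index must be in 0..8, got {graphlet_index}")
    if counts.pair_counts is None:
        raise ValueError("counts lack pair co-occurrences; rerun count_graphlets(include_pairs=True)")
    n = len(counts.nodes)
    theta = THETA[graphlet_index]
    mat = np.zeros((n, n), dtype=float)
    for (i, j), c in counts.pair_counts[graphlet_index].items():
        val = c / theta
        mat[i, j] = val
        mat[j, i] = val
    return GraphletAdjacency(
        graphlet_index=graphlet_index,
        nodes=counts.nodes,
        matrix=mat,
        degree_diag=counts.node_counts[:, graphlet_index].astype(float),
        normalized=False,
    )


def normalize_adjacency(adj: GraphletAdjacency) -> GraphletAdjacency:
    """Symmetrically normalize A_Gi to D^{-1/2} A_Gi D^{-1/2}.

    D is the diagonal of graphlet degrees t_u(Gi). Nodes with t_u = 0 give
    zero rows/columns and are handled downstream (they are dropped from
    spectral embeddings).
    """
    if adj.normalized:
        raise ValueError("adjacency is already normalized")
    d = adj.degree_diag
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    mat = adj.matrix * inv_sqrt[:, None] * inv_sqrt[None, :]
    return GraphletAdjacency(
        graphlet_index=adj.graphlet_index,
        nodes=adj.nodes,
        matrix=mat,
        degree_diag=adj.degree_diag,
        normalized=True,
    )
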