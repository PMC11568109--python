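"""Independent oracles used by the tests.

These deliberately take the slow, obviously-correct route (exhaustive
subset enumeration with networkx isomorphism; exact rational arithmetic)
and share no code with the package's implementations.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np

# prototype graphs and the orbit of each prototype node
_PAW = nx.complete_graph(3)
_PAW.add_edge(0, 3)
_DIAMOND = nx.complete_graph(4)
_DIAMOND.remove_edge(0, 1)

PROTOTYPES: dict[int, nx.Graph] = {
    0: nx.path_graph(2),
    1: nx.path_graph(3),
    2: nx.complete_graph(3),
    3: nx.path_graph(4),
    4: nx.star_graph(3),
    5: nx.cycle_graph(4),
    6: _PAW,
    7: _DIAMOND,
    8: nx.complete_graph(4),
}

PROTO_ORBIT: dict[int, dict[int, int]] = {
    0: {0: 0, 1: 0},
    1: {0: 1, 1: 2, 2: 1},
    2: {0: 3, 1: 3, 2: 3},
    3: {0: 4, 1: 5, 2: 5, 3: 4},
    4: {0: 7, 1: 6, 2: 6, 3: 6},
    5: {0: 8, 1: 8, 2: 8, 3: 8},
    6: {0: 11, 1: 10, 2: 10, 3: 9},
    7: {0: 12, 1: 12, 2: 13, 3: 13},
    8: {0: 14, 1: 14, 2: 14, 3: 14},
}


def brute_force_graphlets(graph: nx.Graph, node_order: tuple[str, ...]):
    """Enumerate every 2-4-node subset, keep connected induced subgraphs,
    classify by networkx isomorphism, derive node/pair/orbit counts.

    Returns (node_counts (n,9), orbit_counts (n,15), pair_counts list of
    nine dicts keyed by index pairs).
    """
    idx = {u: i for i, u in enumerate(node_order)}
    n = len(node_order)
    t = np.zeros((n, 9), dtype=int)
    orb = np.zeros((n, 15), dtype=int)
    pairs: list[dict[tuple[int, int], int]] = [dict() for _ in range(9)]
    for k in (2, 3, 4):
        protos = {gi: p for gi, p in PROTOTYPES.items() if p.number_of_nodes() == k}
        for subset in itertools.combinations(node_order, k):
            sub = graph.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            gi = next(
                g for g, p in protos.items() if nx.is_isomorphic(sub, p)
            )
            matcher = nx.algorithms.isomorphism.GraphMatcher(sub, PROTOTYPES[gi])
            mapping = next(matcher.isomorphisms_iter())
            for u in subset:
                t[idx[u], gi] += 1
                orb[idx[u], PROTO_ORBIT[gi][mapping[u]]] += 1
            for u, v in itertools.combinations(subset, 2):
                i, j = idx[u], idx[v]
                key = (i, j) if i < j else (j, i)
                pairs[gi][key] = pairs[gi].get(key, 0) + 1
    return t, orb, pairs


def exact_hypergeom_sf(k: int, M: int, K: int, n: int) -> Fraction:
    """P(X >= k) for a hypergeometric(M, K, n), exact rational arithmetic."""
    total = math.comb(M, n)
    acc = Fraction(0)
    for i in range(max(k, 0), min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(M - K, n - i), total)
    return acc


def bh_adjust(p: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up, written out by hand."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
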