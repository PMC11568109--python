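"""Seeded synthetic fixtures: networks with known planted structure.

Three generators cover the structures the pipeline assumes, so that every
stage can be exercised without external data:

* :func:`planted_module_fixture` — stochastic-block networks with one
  annotation term planted per module, emulating the modular organization
  of genetic interaction networks;
* :func:`duplication_fixture` — scale-free gene-duplication growth with
  every (child, parent) duplication recorded as a planted paralog pair
  (duplications create triangles via shared neighbours);
* :func:`scale_free_fixture` — preferential-attachment networks with a
  power-law degree tail.

All generators are pure functions of their parameters and seed: the same
inputs regenerate byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .models import generate_sfgd
from .network import Network
from .paralogs import ParalogPairs
from .safe import AnnotationSet

__all__ = [
    "Fixture",
    "planted_module_fixture",
    "duplication_fixture",
    "scale_free_fixture",
]


@dataclass(frozen=True)
class Fixture:
    """A synthetic network plus its planted ground truth."""

    network: Network
    seed: int
    annotations: AnnotationSet | None = None
    paralogs: ParalogPairs | None = None
    truth: dict = field(default_factory=dict)


def planted_module_fixture(
    n_modules: int,
    module_size: int,
    p_in: float,
    p_out: float,
    seed: int,
) -> Fixture:
    """Stochastic-block network with one annotation term per module.

    Within-module edges appear with probability ``p_in``, between-module
    edges with ``p_out`` (``0 <= p_out < p_in <= 1``). If the result is
    disconnected only the largest component is kept and the planted truth
    (and term gene sets) are restricted accordingly.
    """
    if not 0.0 <= p_out < p_in <= 1.0:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    n = n_modules * module_size
    width = len(str(n - 1))
    labels = [f"g{i:0{width}d}" for i in range(n)]
    module_of = {labels[i]: i // module_size for i in range(n)}
    rng = np.random.default_rng(seed)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if module_of[labels[i]] == module_of[labels[j]] else p_out
            if rng.random() < p:
                edges.append((labels[i], labels[j]))
    net = Network(edges, nodes=labels)
    comps = net.connected_components()
    if len(comps) > 1 and p_out > 0.0:
        net = net.subgraph(comps[0])
    elif p_out == 0.0:
        # disjoint cliques/modules are a legitimate fixture; keep everything
        pass
    kept = set(net.nodes)
    membership = {u: m for u, m in module_of.items() if u in kept}
    terms = {}
    for m in range(n_modules):
        genes = frozenset(u for u, mm in membership.items() if mm == m)
        if genes:
            terms[f"module_{m}"] = genes
    ann = AnnotationSet.from_mapping(terms)
    return Fixture(
        network=net,
        seed=seed,
        annotations=ann,
        truth={"membership": membership, "n_modules": n_modules},
    )


def duplication_fixture(
    n_nodes: int,
    p_keep: float,
    p_parent: float,
    seed: int,
) -> Fixture:
    """Gene-duplication network with planted (child, parent) paralog pairs.

    Grows from a connected 2-node seed; each growth step duplicates a
    uniformly chosen node, retaining each parent edge with probability
    ``p_keep`` and adding the child-parent edge with probability
    ``p_parent``. Every duplication event is one planted paralog pair, so
    the pair count is ``n_nodes - 2``.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    net, pairs = generate_sfgd(n_nodes, p_keep, p_parent, seed)
    return Fixture(
        network=net,
        seed=seed,
        paralogs=ParalogPairs.from_pairs(
            pairs, provenance={"generator": "duplication", "p_keep": p_keep, "p_parent": p_parent}
        ),
        truth={"lineage": [tuple(sorted(p)) for p in pairs]},
    )


def scale_free_fixture(n_nodes: int, edges_per_node: int, seed: int) -> Fixture:
    """Preferential-attachment (Barabási–Albert) network.

    Each new node attaches to ``edges_per_node`` existing nodes with
    probability proportional to degree, producing a power-law degree tail
    whose exponent is recoverable by the continuous ML estimator.
    """
    if edges_per_node < 1:
        raise ValueError("edges_per_node must be >= 1")
    g = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=int(seed))
    net = Network.from_integer_edges(sorted(tuple(sorted(e)) for e in g.edges()), n_nodes)
    return Fixture(network=net, seed=seed, truth={"edges_per_node": edges_per_node})
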