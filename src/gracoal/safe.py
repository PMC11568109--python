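"""Spatial Analysis of Functional Enrichment (SAFE) over arbitrary 2D embeddings.

Given a network, a 2D embedding of its nodes and gene-to-term annotations,
SAFE finds regions of the embedding where annotations are over-represented:

1. each network edge is weighted by the Euclidean distance between its
   endpoints in the embedding, and weighted shortest-path distances (WSPD)
   are computed between all node pairs;
2. the local neighbourhood of a node is the node itself plus every node at
   WSPD strictly below a threshold alpha, tuned so the mean neighbourhood
   size hits a target (default 50);
3. each neighbourhood is tested for over-representation of every annotation
   with an upper-tail hypergeometric test over the annotated nodes only,
   with Benjamini–Hochberg correction across terms within the
   neighbourhood; a term is *enriched* if significant in at least one
   neighbourhood, a gene is *enriched* if at least one term is significant
   in its own neighbourhood;
4. terms enriched in overlapping neighbourhood sets are clustered
   (average-linkage on 1 - Jaccard) into functional *domains*, each
   summarized by its five most frequent name words.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .embeddings import CartesianEmbedding, DiskEmbedding
from .network import Network

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "NeighbourhoodMap",
    "EnrichmentResult",
    "Domain",
    "DomainSet",
    "weight_edges",
    "all_pairs_wspd",
    "tune_alpha",
    "build_neighbourhoods",
    "neighbourhood_enrichment",
    "enrichment_summary",
    "union_enrichment",
    "build_domains",
    "max_jaccard_overlap",
    "run_safe",
    "DEFAULT_STOPWORDS",
]

#: built-in stop words for domain keywords: common English function words
#: plus annotation-name boilerplate; overridable in build_domains
DEFAULT_STOPWORDS = frozenset(
    """a an the of via by to in and or for with on at from into is are as
    process regulation positive negative pathway involved""".split()
)


@dataclass(frozen=True)
class AnnotationSet:
    """Gene-set annotations: term -> genes, with the reverse map derived."""

    term_to_genes: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_mapping(
        cls,
        mapping: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> "AnnotationSet":
        terms = {t: frozenset(g) for t, g in mapping.items() if len(frozenset(g)) > 0}
        if not terms:
            raise ValueError("annotation set has no nonempty terms")
        return cls(terms, dict(descriptions or {}))

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(sorted(self.term_to_genes))

    def gene_to_terms(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for t, genes in self.term_to_genes.items():
            for g in genes:
                out.setdefault(g, set()).add(t)
        return {g: frozenset(ts) for g, ts in out.items()}

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.term_to_genes.values():
            out |= genes
        return frozenset(out)

    def restricted_to(self, keep: Iterable[str]) -> "AnnotationSet":
        """Drop genes outside `keep`; terms left empty are removed (logged)."""
        keep_set = frozenset(keep)
        ignored = len(self.genes() - keep_set)
        if ignored:
            logger.info("ignoring %d annotated genes absent from the network", ignored)
        terms = {}
        for t, genes in sorted(self.term_to_genes.items()):
            g = genes & keep_set
            if g:
                terms[t] = g
            else:
                logger.info("term %s has no genes in the network; skipped", t)
        if not terms:
            raise ValueError("no annotated genes present in the network")
        return AnnotationSet(terms, self.descriptions)


@dataclass(frozen=True)
class NeighbourhoodMap:
    """Per-node local neighbourhoods at WSPD threshold alpha."""

    neighbourhoods: dict[str, frozenset[str]]
    alpha: float

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.neighbourhoods))

    def mean_size(self) -> float:
        return float(np.mean([len(s) for s in self.neighbourhoods.values()]))


@dataclass(frozen=True)
class EnrichmentResult:
    """Raw and BH-adjusted hypergeometric p-values per (neighbourhood, term).

    ``raw_p`` and ``adj_p`` are (n_nodes, n_terms) arrays in the order of
    ``nodes`` and ``terms``. Significance threshold for "enriched" is
    ``significance`` on the adjusted p-value.
    """

    nodes: tuple[str, ...]
    terms: tuple[str, ...]
    raw_p: np.ndarray
    adj_p: np.ndarray
    annotated_nodes: frozenset[str]
    significance: float = 0.05

    def significant_mask(self) -> np.ndarray:
        return self.adj_p < self.significance

    def enriched_terms(self) -> dict[str, frozenset[str]]:
        """term -> neighbourhoods (by centre node) where it is enriched."""
        sig = self.significant_mask()
        out = {}
        for j, t in enumerate(self.terms):
            rows = np.flatnonzero(sig[:, j])
            if rows.size:
                out[t] = frozenset(self.nodes[i] for i in rows)
        return out

    def enriched_genes(self) -> frozenset[str]:
        """Annotated genes with >= 1 enriched term in their own neighbourhood."""
        sig = self.significant_mask().any(axis=1)
        return frozenset(
            u for i, u in enumerate(self.nodes) if sig[i] and u in self.annotated_nodes
        )

    def term_neighbourhood_counts(self) -> dict[str, int]:
        sig = self.significant_mask()
        return {t: int(sig[:, j].sum()) for j, t in enumerate(self.terms)}


@dataclass(frozen=True)
class Domain:
    terms: tuple[str, ...]
    keywords: tuple[str, ...]
    neighbourhoods: frozenset[str]


@dataclass(frozen=True)
class DomainSet:
    domains: tuple[Domain, ...]
    min_neighbourhoods: int
    cut_fraction: float


# ---------------------------------------------------------------------------
# steps 1-2: distances and neighbourhoods


def _coords_lookup(cart: CartesianEmbedding | DiskEmbedding) -> dict[str, tuple[float, float]]:
    if isinstance(cart, DiskEmbedding):
        cart = cart.to_cartesian()
    return cart.as_dict()


def weight_edges(network: Network, cart: CartesianEmbedding | DiskEmbedding) -> nx.Graph:
    """Weight each network edge by the endpoints' embedding distance.

    Disk embeddings are converted with x = r sin(angle), y = r cos(angle).
    Coincident endpoints get weight 1e-12 so shortest paths stay
    well-defined (logged). Nodes without coordinates raise.
    """
    pos = _coords_lookup(cart)
    missing = [u for u in network.nodes if u not in pos]
    if missing:
        raise ValueError(f"nodes without embedding coordinates: {missing[:10]}")
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    n_zero = 0
    for u, v in network.edges:
        (x1, y1), (x2, y2) = pos[u], pos[v]
        w = float(np.hypot(x1 - x2, y1 - y2))
        if w == 0.0:
            w = 1e-12
            n_zero += 1
        g.add_edge(u, v, weight=w)
    if n_zero:
        logger.info("%d coincident edge endpoints set to epsilon weight", n_zero)
    return g


def all_pairs_wspd(weighted: nx.Graph) -> tuple[tuple[str, ...], np.ndarray]:
    """Exact all-pairs weighted shortest-path distances.

    Returns node labels in sorted order and the symmetric distance matrix;
    unreachable pairs are +inf.
    """
    nodes = tuple(sorted(weighted.nodes))
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for u, v, data in weighted.edges(data=True):
        i, j = idx[u], idx[v]
        rows += [i, j]
        cols += [j, i]
        vals += [data["weight"], data["weight"]]
    mat = csr_matrix((vals, (rows, cols)), shape=(n, n))
    dist = dijkstra(mat, directed=False)
    return nodes, dist


def tune_alpha(
    dist: np.ndarray, target_mean_size: int = 50
) -> tuple[float, float]:
    """Smallest alpha whose mean neighbourhood size reaches the target.

    Bisects over the sorted finite distance values; neighbourhood
    membership is *strict* (WSPD < alpha) plus the node itself, so the mean
    size is a step function of alpha and the search is exact. Returns
    (alpha, achieved mean size). If the target is unreachable the largest
    finite distance plus a margin is returned with a warning.
    """
    n = dist.shape[0]
    if not 1 <= target_mean_size <= n:
        raise ValueError(f"target mean size must be in [1, {n}]")
    finite = dist[np.isfinite(dist)]
    positives = np.unique(finite[finite > 0])
    candidates = np.concatenate([[0.0], positives])

    def mean_size(thr: float) -> float:
        # closure at thr: members with d <= thr (self included via d=0)
        return float((dist <= thr).sum(axis=1).mean())

    lo, hi = 0, len(candidates) - 1
    if mean_size(candidates[hi]) < target_mean_size:
        logger.warning(
            "target mean neighbourhood size %d unreachable; using max distance",
            target_mean_size,
        )
        return float(candidates[hi] + 1.0), mean_size(candidates[hi])
    while lo < hi:
        mid = (lo + hi) // 2
        if mean_size(candidates[mid]) >= target_mean_size:
            hi = mid
        else:
            lo = mid + 1
    thr = candidates[lo]
    nxt = positives[positives > thr]
    alpha = float((thr + nxt[0]) / 2.0) if nxt.size else float(thr + 1.0)
    return alpha, mean_size(thr)


def build_neighbourhoods(
    nodes: Sequence[str], dist: np.ndarray, alpha: float
) -> NeighbourhoodMap:
    """Neighbourhood of u = {u} plus all v with WSPD(u, v) strictly < alpha."""
    nbhd = {}
    for i, u in enumerate(nodes):
        members = {nodes[j] for j in np.flatnonzero(dist[i] < alpha)}
        members.add(u)
        nbhd[u] = frozenset(members)
    return NeighbourhoodMap(nbhd, float(alpha))


# ---------------------------------------------------------------------------
# step 3: hypergeometric enrichment


def neighbourhood_enrichment(
    nbhd: NeighbourhoodMap,
    ann: AnnotationSet,
    significance: float = 0.05,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment per (neighbourhood, term).

    The population is the set of *annotated* nodes among the
    neighbourhood-map nodes; unannotated nodes contribute nothing to the
    counts. Benjamini–Hochberg correction is applied across terms within
    each neighbourhood.
    """
    nodes = nbhd.nodes
    ann = ann.restricted_to(nodes)
    annotated = frozenset(ann.genes())
    if not annotated:
        raise ValueError("no annotated nodes in the network")
    terms = ann.terms
    m_total = len(annotated)
    term_genes = [ann.term_to_genes[t] for t in terms]
    raw = np.ones((len(nodes), len(terms)))
    for i, u in enumerate(nodes):
        sample = nbhd.neighbourhoods[u] & annotated
        n_u = len(sample)
        if n_u == 0:
            continue
        for j, genes in enumerate(term_genes):
            k = len(sample & genes)
            raw[i, j] = float(hypergeom.sf(k - 1, m_total, len(genes), n_u))
    adj = np.ones_like(raw)
    for i in range(raw.shape[0]):
        adj[i] = multipletests(raw[i], method="fdr_bh")[1]
    adj = np.maximum(adj, raw)  # guard against fp rounding below raw p
    return EnrichmentResult(
        nodes=nodes,
        terms=terms,
        raw_p=raw,
        adj_p=adj,
        annotated_nodes=annotated,
        significance=significance,
    )


def enrichment_summary(
    res: EnrichmentResult,
    ann: AnnotationSet,
    all_annotated_genes: Iterable[str] | None = None,
) -> dict[str, float]:
    """Counts and percentages of enriched genes and terms.

    The gene denominator defaults to every annotated gene passed in
    ``all_annotated_genes`` (e.g. including genes dropped from the
    embedding, which can never be enriched); falls back to the annotated
    genes of the embedded component.
    """
    enriched_g = res.enriched_genes()
    denom_genes = frozenset(all_annotated_genes) if all_annotated_genes is not None else res.annotated_nodes
    n_terms_total = len(ann.terms)
    enriched_t = res.enriched_terms()
    n_gene_den = max(len(denom_genes), 1)
    return {
        "n_enriched_genes": float(len(enriched_g)),
        "n_annotated_genes": float(len(denom_genes)),
        "pct_enriched_genes": 100.0 * len(enriched_g) / n_gene_den,
        "n_enriched_terms": float(len(enriched_t)),
        "n_terms": float(n_terms_total),
        "pct_enriched_terms": 100.0 * len(enriched_t) / max(n_terms_total, 1),
    }


def union_enrichment(results: Iterable[EnrichmentResult]) -> frozenset[str]:
    """Union of enriched genes across runs (e.g. across graphlet indices)."""
    out: set[str] = set()
    for res in results:
        out |= res.enriched_genes()
    return frozenset(out)


# ---------------------------------------------------------------------------
# step 4: functional domains


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def _keywords(
    terms: Sequence[str],
    descriptions: Mapping[str, str],
    stopwords: frozenset[str],
    k: int = 5,
) -> tuple[str, ...]:
    freq: dict[str, int] = {}
    for t in terms:
        name = descriptions.get(t) or t
        for w in re.split(r"[^0-9A-Za-z']+", name.lower()):
            if w and w not in stopwords and not w.isdigit():
                freq[w] = freq.get(w, 0) + 1
    ranked = sorted(freq, key=lambda w: (-freq[w], w))
    return tuple(ranked[:k])


def build_domains(
    res: EnrichmentResult,
    min_neighbourhoods: int = 10,
    cut_fraction: float = 0.75,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    descriptions: Mapping[str, str] | None = None,
) -> DomainSet:
    """Aggregate enriched terms into functional domains.

    Terms enriched in fewer than ``min_neighbourhoods`` neighbourhoods are
    discarded; the rest are clustered by average-linkage agglomerative
    clustering on 1 - Jaccard of their enriched-neighbourhood sets, and the
    dendrogram is cut at ``cut_fraction`` of its maximum merge height. Each
    domain is summarized by its five most frequent name words after
    stop-word removal (ties alphabetical).
    """
    descriptions = dict(descriptions or {})
    counts = res.term_neighbourhood_counts()
    profiles = res.enriched_terms()
    retained = sorted(t for t, c in counts.items() if c >= min_neighbourhoods)
    if not retained:
        logger.warning(
            "no term enriched in >= %d neighbourhoods; empty domain set",
            min_neighbourhoods,
        )
        return DomainSet((), min_neighbourhoods, cut_fraction)
    if len(retained) == 1:
        t = retained[0]
        dom = Domain((t,), _keywords([t], descriptions, stopwords), profiles[t])
        return DomainSet((dom,), min_neighbourhoods, cut_fraction)
    m = len(retained)
    cond = []
    for i in range(m):
        for j in range(i + 1, m):
            cond.append(1.0 - _jaccard(profiles[retained[i]], profiles[retained[j]]))
    link = linkage(np.asarray(cond), method="average")
    max_h = float(link[:, 2].max())
    if max_h <= 0.0:
        labels = np.ones(m, dtype=int)
    else:
        labels = fcluster(link, t=cut_fraction * max_h, criterion="distance")
    by_label: dict[int, list[str]] = {}
    for t, lab in zip(retained, labels):
        by_label.setdefault(int(lab), []).append(t)
    domains = []
    for lab in sorted(by_label, key=lambda L: sorted(by_label[L])[0]):
        ts = tuple(sorted(by_label[lab]))
        prof = frozenset().union(*(profiles[t] for t in ts))
        domains.append(Domain(ts, _keywords(ts, descriptions, stopwords), prof))
    return DomainSet(tuple(domains), min_neighbourhoods, cut_fraction)


def max_jaccard_overlap(
    domains_by_run: Mapping[str, DomainSet]
) -> dict[tuple[str, int], float]:
    """Per-domain maximum Jaccard overlap against domains of *other* runs.

    Keyed by (run name, domain position); a value of 0.0 marks a domain
    whose term set is completely unique to its run.
    """
    if len(domains_by_run) < 2:
        raise ValueError("need domain sets from at least two runs")
    out: dict[tuple[str, int], float] = {}
    for run, dset in domains_by_run.items():
        for i, dom in enumerate(dset.domains):
            best = 0.0
            mine = frozenset(dom.terms)
            for other_run, other_set in domains_by_run.items():
                if other_run == run:
                    continue
                for odom in other_set.domains:
                    best = max(best, _jaccard(mine, frozenset(odom.terms)))
            out[(run, i)] = best
    return out


# ---------------------------------------------------------------------------
# one-call pipeline


def run_safe(
    network: Network,
    embedding: CartesianEmbedding | DiskEmbedding,
    ann: AnnotationSet,
    target_mean_size: int = 50,
    significance: float = 0.05,
) -> tuple[EnrichmentResult, NeighbourhoodMap]:
    """SAFE steps 1-3 on the subnetwork covered by the embedding.

    Nodes dropped from the embedding are excluded here (they can never be
    enriched); keep them in the gene denominator via
    :func:`enrichment_summary` when comparing embeddings.
    """
    embedded = set(embedding.nodes)
    sub = network.subgraph(embedded & set(network.nodes))
    weighted = weight_edges(sub, embedding)
    nodes, dist = all_pairs_wspd(weighted)
    target = min(target_mean_size, len(nodes))
    alpha, _ = tune_alpha(dist, target)
    nbhd = build_neighbourhoods(nodes, dist, alpha)
    res = neighbourhood_enrichment(nbhd, ann, significance=significance)
    return res, nbhd
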