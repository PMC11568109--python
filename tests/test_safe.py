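"""SAFE pipeline: distances, neighbourhoods, enrichment, domains."""

import math

import numpy as np
import pytest

from gracoal.embeddings import CartesianEmbedding
from gracoal.network import Network
from gracoal.safe import (
    AnnotationSet,
    NeighbourhoodMap,
    all_pairs_wspd,
    build_domains,
    build_neighbourhoods,
    enrichment_summary,
    max_jaccard_overlap,
    neighbourhood_enrichment,
    tune_alpha,
    union_enrichment,
    weight_edges,
)

from ._oracles import bh_adjust, exact_hypergeom_sf


def _path_abc():
    net = Network([("a", "b"), ("b", "c")])
    cart = CartesianEmbedding(
        ("a", "b", "c"), np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
    )
    return net, cart


class TestWeightEdges:
    def test_euclidean_345(self):
        net = Network([("a", "b")])
        cart = CartesianEmbedding(("a", "b"), np.array([[0.0, 0.0], [3.0, 4.0]]))
        g = weight_edges(net, cart)
        assert g["a"]["b"]["weight"] == 5.0

    def test_coincident_endpoints_get_epsilon(self):
        net = Network([("a", "b")])
        cart = CartesianEmbedding(("a", "b"), np.zeros((2, 2)))
        g = weight_edges(net, cart)
        assert g["a"]["b"]["weight"] == 1e-12

    def test_unit_circle_chord_lengths(self):
        n = 8
        nodes = tuple(f"n{i}" for i in range(n))
        coords = np.array(
            [[math.sin(2 * math.pi * k / n), math.cos(2 * math.pi * k / n)] for k in range(n)]
        )
        net = Network([(nodes[i], nodes[(i + 1) % n]) for i in range(n)])
        g = weight_edges(net, CartesianEmbedding(nodes, coords))
        expected = 2 * math.sin(math.pi / n)
        for u, v, d in g.edges(data=True):
            assert d["weight"] == pytest.approx(expected)

    def test_missing_coordinates_rejected(self):
        net = Network([("a", "b"), ("b", "c")])
        cart = CartesianEmbedding(("a", "b"), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="c"):
            weight_edges(net, cart)


class TestWSPD:
    def test_path_distances_add(self):
        net, cart = _path_abc()
        nodes, dist = all_pairs_wspd(weight_edges(net, cart))
        i, j = nodes.index("a"), nodes.index("c")
        assert dist[i, j] == pytest.approx(3.0)

    def test_disconnected_pair_infinite(self):
        net = Network([("a", "b")], nodes=["z"])
        cart = CartesianEmbedding(("a", "b", "z"), np.array([[0, 0], [1, 0], [5, 5]], float))
        nodes, dist = all_pairs_wspd(weight_edges(net, cart))
        assert np.isinf(dist[nodes.index("a"), nodes.index("z")])

    def test_heavy_edge_bypassed(self):
        net = Network([("a", "b"), ("b", "c"), ("a", "c")])
        import networkx as nx

        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("b", "c", weight=1.0)
        g.add_edge("a", "c", weight=10.0)
        nodes, dist = all_pairs_wspd(g)
        assert dist[nodes.index("a"), nodes.index("c")] == pytest.approx(2.0)


class TestTuneAlpha:
    def test_path_target_two(self):
        # unit path a-b-c: just above distance 1 the sizes are 2,3,2
        dist = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        alpha, mean = tune_alpha(dist, target_mean_size=2)
        assert 1.0 < alpha <= 2.0
        assert mean == pytest.approx(7 / 3)

    def test_target_one_gives_singletons(self):
        dist = np.array([[0, 1], [1, 0]], dtype=float)
        alpha, mean = tune_alpha(dist, target_mean_size=1)
        assert 0.0 < alpha < 1.0
        assert mean == 1.0

    def test_complete_graph_full_target(self):
        n = 5
        dist = np.ones((n, n)) - np.eye(n)
        alpha, mean = tune_alpha(dist, target_mean_size=n)
        assert alpha > 1.0
        assert mean == n

    def test_no_smaller_alpha_reaches_target(self):
        rng = np.random.default_rng(0)
        pts = rng.random((20, 2))
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        alpha, mean = tune_alpha(dist, target_mean_size=8)
        assert mean >= 8
        # the previous candidate (largest distance < alpha) must miss target
        finite = np.unique(dist[dist < alpha])
        below = finite[finite < finite.max()]
        prev_mean = (dist <= below.max()).sum(axis=1).mean()
        assert prev_mean < 8

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            tune_alpha(np.zeros((3, 3)), target_mean_size=4)

    def test_unreachable_target_on_disconnected_graph_warns(self, caplog):
        # two components of 2: no alpha reaches a mean size of 4
        dist = np.full((4, 4), np.inf)
        np.fill_diagonal(dist, 0.0)
        dist[0, 1] = dist[1, 0] = 1.0
        dist[2, 3] = dist[3, 2] = 1.0
        import logging

        with caplog.at_level(logging.WARNING, logger="gracoal.safe"):
            alpha, mean = tune_alpha(dist, target_mean_size=4)
        assert alpha > 1.0
        assert mean == 2.0
        assert "unreachable" in caplog.text


class TestNeighbourhoods:
    def test_strict_inequality_and_self(self):
        dist = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        nbhd = build_neighbourhoods(("a", "b", "c"), dist, alpha=1.5)
        assert nbhd.neighbourhoods["b"] == {"a", "b", "c"}
        assert nbhd.neighbourhoods["a"] == {"a", "b"}
        # membership at exactly alpha excluded
        nb2 = build_neighbourhoods(("a", "b", "c"), dist, alpha=1.0)
        assert nb2.neighbourhoods["a"] == {"a"}


class TestEnrichment:
    def test_exact_combinatorial_pvalue(self):
        # 20 annotated genes; term covers 5; neighbourhood = exactly those 5
        genes = [f"g{i:02d}" for i in range(20)]
        term_genes = genes[:5]
        ann = AnnotationSet.from_mapping({"T": term_genes, "bg": genes})
        nbhd = NeighbourhoodMap(
            {g: frozenset(term_genes) if g in term_genes else frozenset({g}) for g in genes},
            alpha=1.0,
        )
        res = neighbourhood_enrichment(nbhd, ann)
        j = res.terms.index("T")
        i = res.nodes.index("g00")
        assert res.raw_p[i, j] == pytest.approx(1 / 15504, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exact_rational_oracle(self, seed):
        """scipy hypergeometric tail vs exact Fraction arithmetic, pop <= 30."""
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(rng.integers(8, 30))]
        n_terms = 4
        mapping = {}
        for t in range(n_terms):
            k = int(rng.integers(1, len(genes)))
            mapping[f"T{t}"] = list(rng.choice(genes, size=k, replace=False))
        ann = AnnotationSet.from_mapping(mapping)
        nbhds = {}
        for g in genes:
            k = int(rng.integers(1, len(genes)))
            members = set(rng.choice(genes, size=k, replace=False)) | {g}
            nbhds[g] = frozenset(members)
        res = neighbourhood_enrichment(NeighbourhoodMap(nbhds, 1.0), ann)
        annotated = res.annotated_nodes
        M = len(annotated)
        for i, u in enumerate(res.nodes):
            sample = nbhds[u] & annotated
            for j, t in enumerate(res.terms):
                K = len(ann.term_to_genes[t] & annotated)
                k_obs = len(sample & ann.term_to_genes[t])
                exact = float(exact_hypergeom_sf(k_obs, M, K, len(sample)))
                assert abs(res.raw_p[i, j] - exact) < 1e-12

    def test_term_covering_everything_never_significant(self):
        genes = ["a", "b", "c", "d"]
        ann = AnnotationSet.from_mapping({"all": genes})
        nbhd = NeighbourhoodMap({g: frozenset(genes) for g in genes}, 1.0)
        res = neighbourhood_enrichment(nbhd, ann)
        assert (res.raw_p == 1.0).all()

    def test_bh_worked_example(self):
        adj = bh_adjust([0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.03, 0.03, 0.04])
        # implementation path: inject raw p's through statsmodels agreement
        from statsmodels.stats.multitest import multipletests

        impl = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert impl == pytest.approx(adj)

    @pytest.mark.parametrize("seed", [3, 9])
    def test_bh_adjustment_matches_hand_rolled_stepup(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.random(17)
        from statsmodels.stats.multitest import multipletests

        assert multipletests(raw, method="fdr_bh")[1] == pytest.approx(bh_adjust(list(raw)))

    def test_adjusted_at_least_raw(self):
        genes = [f"g{i}" for i in range(12)]
        ann = AnnotationSet.from_mapping({"A": genes[:4], "B": genes[4:9], "C": genes[2:7]})
        nbhd = NeighbourhoodMap(
            {g: frozenset(genes[max(0, i - 3) : i + 4]) for i, g in enumerate(genes)}, 1.0
        )
        res = neighbourhood_enrichment(nbhd, ann)
        assert (res.adj_p >= res.raw_p).all()

    def test_no_annotated_nodes_rejected(self):
        ann = AnnotationSet.from_mapping({"T": ["x", "y"]})
        nbhd = NeighbourhoodMap({"a": frozenset({"a"})}, 1.0)
        with pytest.raises(ValueError):
            neighbourhood_enrichment(nbhd, ann)


class TestSummaryAndUnion:
    def _result(self, sig_nodes, all_nodes, terms=("T",)):
        n, t = len(all_nodes), len(terms)
        raw = np.ones((n, t))
        adj = np.ones((n, t))
        for u in sig_nodes:
            adj[all_nodes.index(u), 0] = 0.01
        return __import__("gracoal.safe", fromlist=["EnrichmentResult"]).EnrichmentResult(
            tuple(all_nodes), tuple(terms), raw, adj, frozenset(all_nodes)
        )

    def test_percentages(self):
        nodes = [f"g{i}" for i in range(12)]
        res = self._result(nodes[:3], nodes)
        ann = AnnotationSet.from_mapping({"T": nodes})
        s = enrichment_summary(res, ann)
        assert s["pct_enriched_genes"] == pytest.approx(25.0)
        assert s["pct_enriched_terms"] == pytest.approx(100.0)

    def test_empty_enrichment_zero_percent(self):
        nodes = ["a", "b"]
        res = self._result([], nodes)
        ann = AnnotationSet.from_mapping({"T": nodes})
        assert enrichment_summary(res, ann)["pct_enriched_genes"] == 0.0

    def test_union_is_set_union_and_idempotent(self):
        nodes = ["a", "b", "c"]
        r1 = self._result(["a", "b"], nodes)
        r2 = self._result(["b", "c"], nodes)
        assert union_enrichment([r1, r2]) == {"a", "b", "c"}
        assert union_enrichment([r1] * 9) == union_enrichment([r1])
        assert union_enrichment([r1, self._result([], nodes)]) == {"a", "b"}


class TestDomains:
    def _result_with_profiles(self, profiles, n_nodes=30):
        nodes = tuple(f"n{i:02d}" for i in range(n_nodes))
        terms = tuple(sorted(profiles))
        raw = np.ones((n_nodes, len(terms)))
        adj = np.ones((n_nodes, len(terms)))
        for j, t in enumerate(terms):
            for i in profiles[t]:
                adj[i, j] = 0.001
        from gracoal.safe import EnrichmentResult

        return EnrichmentResult(nodes, terms, raw, adj, frozenset(nodes))

    def test_jaccard_based_grouping(self):
        # A and B share all neighbourhoods (JI=1); C shares none
        common = set(range(12))
        res = self._result_with_profiles({"A": common, "B": common, "C": set(range(15, 28))})
        ds = build_domains(res, min_neighbourhoods=10, cut_fraction=0.75)
        groups = sorted(tuple(d.terms) for d in ds.domains)
        assert groups == [("A", "B"), ("C",)]

    def test_low_support_terms_discarded(self):
        res = self._result_with_profiles({"A": set(range(12)), "rare": {0, 1}})
        ds = build_domains(res, min_neighbourhoods=10)
        assert [d.terms for d in ds.domains] == [("A",)]

    def test_no_retained_terms_warns_empty(self):
        res = self._result_with_profiles({"rare": {0}})
        ds = build_domains(res, min_neighbourhoods=10)
        assert ds.domains == ()

    def test_keywords_frequency_then_alphabetical(self):
        common = set(range(12))
        res = self._result_with_profiles(
            {
                "alpha beta gamma": common,
                "beta gamma delta": common,
                "beta epsilon zeta": common,
            }
        )
        ds = build_domains(res, min_neighbourhoods=10)
        (dom,) = ds.domains
        assert dom.keywords[0] == "beta"  # appears 3x
        assert dom.keywords[1] == "gamma"  # 2x beats the 1x words
        assert set(dom.keywords) <= {"beta", "gamma", "alpha", "delta", "epsilon", "zeta"}
        assert len(dom.keywords) == 5

    def test_stopwords_removed(self):
        common = set(range(12))
        res = self._result_with_profiles({"regulation of transport": common})
        ds = build_domains(res, min_neighbourhoods=10)
        assert ds.domains[0].keywords == ("transport",)


class TestMaxJaccard:
    def test_identical_and_disjoint_and_partial(self):
        from gracoal.safe import Domain, DomainSet

        def dset(*term_groups):
            return DomainSet(
                tuple(Domain(tuple(g), (), frozenset()) for g in term_groups), 10, 0.75
            )

        runs = {
            "r1": dset(("A", "B")),
            "r2": dset(("A", "B"), ("X",)),
            "r3": dset(("B", "C")),
        }
        mj = max_jaccard_overlap(runs)
        assert mj[("r1", 0)] == 1.0  # identical domain in r2
        assert mj[("r2", 1)] == 0.0  # X is completely unique
        assert mj[("r3", 0)] == pytest.approx(1 / 3)  # {B,C} vs {A,B}

    def test_requires_two_runs(self):
        from gracoal.safe import DomainSet

        with pytest.raises(ValueError):
            max_jaccard_overlap({"only": DomainSet((), 10, 0.75)})
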