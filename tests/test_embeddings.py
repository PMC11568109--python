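"""Spectral, angular/radial, power-law fit, GraCoal and GraSpring."""

import itertools
import math

import numpy as np
import pytest

from gracoal.embeddings import (
    CartesianEmbedding,
    PowerLawFit,
    angular_coordinates,
    coalescent_embed,
    fit_power_law,
    gracoal_embed,
    graphlet_spectral_embedding,
    graspring_embed,
    radial_coalescent,
    radial_gracoal,
    spectral_embed,
)
from gracoal.graphlets import count_graphlets, graphlet_adjacency, normalize_adjacency
from gracoal.network import Network

from .conftest import random_er_network


def _normalized(net: Network, gi: int):
    return normalize_adjacency(graphlet_adjacency(count_graphlets(net), gi))


class TestSpectral:
    def test_path_orders_nodes_monotonically(self, path3):
        cart = graphlet_spectral_embedding(_normalized(path3, 0), dim=1)
        coord = {u: x for u, (x,) in zip(cart.nodes, cart.coords[:, :1])}
        # Fiedler vector of the path separates the two ends, middle between
        assert coord["a"] > coord["b"] > coord["c"] or coord["a"] < coord["b"] < coord["c"]

    def test_triangle_symmetric_distances(self, triangle):
        cart = graphlet_spectral_embedding(_normalized(triangle, 2), dim=2)
        d = [
            np.linalg.norm(cart.coords[i] - cart.coords[j])
            for i, j in itertools.combinations(range(3), 2)
        ]
        assert np.allclose(d, d[0])

    def test_unnormalized_rejected(self, triangle):
        with pytest.raises(ValueError, match="normalized"):
            graphlet_spectral_embedding(graphlet_adjacency(count_graphlets(triangle), 2))

    def test_too_small_component_rejected(self, path3):
        with pytest.raises(ValueError, match="at least"):
            graphlet_spectral_embedding(_normalized(path3, 0), dim=3)

    def test_zero_count_nodes_dropped(self, paw):
        cart = graphlet_spectral_embedding(_normalized(paw, 2), dim=2)
        assert set(cart.nodes) == {"a", "b", "c"}
        assert cart.dropped == ("d",)


class TestAngular:
    def test_cardinal_points_ranked_from_pole(self):
        cart = CartesianEmbedding(
            ("a", "b", "c", "d"),
            np.array([[0, 1], [1, 0], [0, -1], [-1, 0]], dtype=float),
        )
        ang = angular_coordinates(cart)
        assert ang == {
            "a": 0.0,
            "b": math.pi / 2,
            "c": math.pi,
            "d": 3 * math.pi / 2,
        }

    @pytest.mark.parametrize("seed", [0, 4])
    def test_angle_multiset_is_equidistant(self, seed):
        rng = np.random.default_rng(seed)
        n = 11
        cart = CartesianEmbedding(
            tuple(f"n{i}" for i in range(n)), rng.normal(size=(n, 2))
        )
        ang = sorted(angular_coordinates(cart).values())
        assert np.allclose(ang, [2 * math.pi * k / n for k in range(n)])

    def test_tie_broken_by_label(self):
        cart = CartesianEmbedding(
            ("a", "b"), np.array([[1.0, 1.0], [1.0, 1.0]])
        )
        ang = angular_coordinates(cart)
        assert ang["a"] == 0.0 and ang["b"] == math.pi

    def test_origin_node_gets_pole_angle(self):
        cart = CartesianEmbedding(
            ("mid", "right"), np.array([[0.0, 0.0], [1.0, 0.0]])
        )
        ang = angular_coordinates(cart)
        assert ang["mid"] == 0.0  # raw angle 0 ranks first


class TestRadial:
    def test_gracoal_log_rank(self):
        r = radial_gracoal({"a": 5, "b": 3, "c": 1})
        assert r["a"] == 0.0
        assert r["b"] == pytest.approx(math.log(2))
        assert r["c"] == pytest.approx(math.log(3))

    def test_single_node(self):
        assert radial_gracoal({"only": 7}) == {"only": 0.0}

    def test_tie_break_by_label(self):
        r = radial_gracoal({"b": 2, "a": 2})
        assert r["a"] == 0.0 and r["b"] == pytest.approx(math.log(2))

    def test_monotone_in_counts(self):
        counts = {f"n{i}": 100 - i for i in range(30)}
        r = radial_gracoal(counts)
        for i in range(29):
            assert r[f"n{i}"] < r[f"n{i+1}"]

    def test_coalescent_rank1(self):
        # N=4, lambda=3 => beta=1/2; rank-1 radius = 0.5 ln 4 = ln 2
        r = radial_coalescent({"a": 9, "b": 5, "c": 3, "d": 1}, PowerLawFit(3.0))
        assert r["a"] == pytest.approx(math.log(2))

    def test_coalescent_rank_n_is_log_n(self):
        for lam in (2.0, 2.5, 3.0):
            r = radial_coalescent({"a": 3, "b": 2, "c": 1}, PowerLawFit(lam))
            assert r["c"] == pytest.approx(math.log(3))

    def test_beta_one_reduces_to_gracoal(self):
        vals = {"a": 10, "b": 6, "c": 2, "d": 1}
        ce = radial_coalescent(vals, PowerLawFit(2.0))  # beta = 1
        gc = radial_gracoal(vals)
        assert all(ce[u] == pytest.approx(gc[u]) for u in vals)


class TestPowerLawFit:
    def test_two_point_closed_form(self):
        # degrees {1, e}: lambda = 1 + 2/1 = 3
        fit = fit_power_law([1.0, math.e])
        assert fit.lambda_hat == pytest.approx(3.0)

    def test_all_ones_clamped(self):
        with pytest.warns(UserWarning, match="clamp"):
            fit = fit_power_law([1, 1, 1])
        assert fit.lambda_hat == 1.5 and fit.beta == pytest.approx(2.0)

    def test_recovers_exponent_from_samples(self):
        # inverse-CDF sampling of a continuous power law, lambda = 2.5
        rng = np.random.default_rng(1234)
        u = rng.random(10_000)
        samples = (1.0 - u) ** (-1.0 / 1.5)
        fit = fit_power_law(samples)
        assert abs(fit.lambda_hat - 2.5) < 0.1

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            fit_power_law([2])
        with pytest.raises(ValueError):
            fit_power_law([0.5, 2.0])


class TestGraCoalEmbed:
    def test_deterministic(self, k4):
        a = gracoal_embed(k4, 2)
        b = gracoal_embed(k4, 2)
        assert a.nodes == b.nodes
        assert (a.angles == b.angles).all() and (a.radii == b.radii).all()

    def test_star_hub_at_centre(self):
        star = Network([("hub", f"leaf{i}") for i in range(5)])
        d = gracoal_embed(star, 0)
        radius = dict(zip(d.nodes, d.radii))
        assert radius["hub"] == 0.0
        assert all(radius[u] > 0 for u in d.nodes if u != "hub")

    def test_radii_are_log_ranks_when_counts_distinct(self):
        net = random_er_network(14, 0.45, seed=3)
        d = gracoal_embed(net, 0)
        n = len(d.nodes)
        assert sorted(d.radii) == pytest.approx([math.log(k) for k in range(1, n + 1)])

    def test_two_cliques_occupy_disjoint_arcs(self):
        # two 6-cliques joined through a shared triangle so the G2
        # adjacency stays connected; each clique then fills a contiguous
        # angular arc
        edges = [(f"a{i}", f"a{j}") for i, j in itertools.combinations(range(6), 2)]
        edges += [(f"b{i}", f"b{j}") for i, j in itertools.combinations(range(6), 2)]
        edges += [("a0", "b0"), ("a0", "b1"), ("b0", "a1")]
        net = Network(edges)
        d = gracoal_embed(net, 2)
        ang = dict(zip(d.nodes, d.angles))
        arc_a = sorted(a for u, a in ang.items() if u.startswith("a"))
        arc_b = sorted(a for u, a in ang.items() if u.startswith("b"))
        assert arc_a and arc_b
        # one clique's angles all precede the other's (up to rotation)
        gap = 2 * math.pi / len(ang)
        joined = sorted((a, u[0]) for u, a in ang.items())
        labels = "".join(lab for _, lab in joined)
        assert "ab" * 2 not in (labels + labels)  # no interleaving a,b,a,b

    def test_ce_embed_radii_nonnegative_and_angles_equidistant(self):
        net = random_er_network(16, 0.3, seed=8)
        d = coalescent_embed(net)
        assert (d.radii >= 0).all()
        n = len(d.nodes)
        assert sorted(d.angles) == pytest.approx([2 * math.pi * k / n for k in range(n)])


class TestGraSpring:
    def test_zero_iterations_is_identity(self, k4):
        init = spectral_embed(k4, 0)
        out = graspring_embed(k4, 0, init=init, iterations=0)
        assert (out.coords == init.coords).all()

    def test_deterministic(self):
        net = random_er_network(15, 0.3, seed=5)
        a = graspring_embed(net, 0)
        b = graspring_embed(net, 0)
        assert (a.coords == b.coords).all()

    def test_missing_init_nodes_rejected(self, k4):
        bad = CartesianEmbedding(("a",), np.zeros((1, 2)))
        with pytest.raises(ValueError, match="missing"):
            graspring_embed(k4, 0, init=bad)

    def test_two_cliques_separate(self):
        edges = [(f"a{i}", f"a{j}") for i, j in itertools.combinations(range(5), 2)]
        edges += [(f"b{i}", f"b{j}") for i, j in itertools.combinations(range(5), 2)]
        edges += [("a0", "b0")]
        net = Network(edges)
        out = graspring_embed(net, 0, iterations=50)
        pos = out.as_dict()
        intra, inter = [], []
        for u, v in itertools.combinations(out.nodes, 2):
            d = math.dist(pos[u], pos[v])
            (intra if u[0] == v[0] else inter).append(d)
        assert np.mean(intra) < np.mean(inter)
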