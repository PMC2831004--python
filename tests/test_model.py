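import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from p2net.model import (
    Hyperparameters,
    ModelParameters,
    dyad_probabilities_directed,
    edge_probability,
    log_likelihood,
    log_posterior,
    log_prior,
    sociality,
)
from p2net.network_io import network_from_edges


def _params(theta, a, gamma=(), **kw):
    return ModelParameters(theta=theta, gamma=np.asarray(gamma, dtype=float),
                           a=np.asarray(a, dtype=float), **kw)


class TestSociality:
    def test_single_binary_covariate(self):
        p = _params(0.0, a=[0.5], gamma=[0.06])
        assert sociality(p, np.array([[1.0]])) == pytest.approx([0.56])

    def test_zero_gamma_returns_random_effects(self):
        a = np.array([0.3, -1.2, 0.0])
        p = _params(0.0, a=a, gamma=[0.0])
        X = np.ones((3, 1))
        np.testing.assert_allclose(sociality(p, X), a)

    def test_matches_dot_product_for_two_covariates(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((6, 2))
        g = rng.standard_normal(2)
        a = rng.standard_normal(6)
        p = _params(0.0, a=a, gamma=g)
        expected = np.array([g @ X[i] + a[i] for i in range(6)])
        np.testing.assert_allclose(sociality(p, X), expected)

    def test_dimension_mismatch_is_error(self):
        p = _params(0.0, a=[0.0, 0.0], gamma=[1.0, 2.0])
        with pytest.raises(ValueError, match="columns"):
            sociality(p, np.ones((2, 1)))


class TestEdgeProbability:
    def test_paper_density_worked_example(self):
        # theta = -5.68 with zero socialities -> edge probability 0.0034
        p = edge_probability(-5.68, 0.0, 0.0)
        assert float(f"{p:.2g}") == 0.0034

    def test_zero_parameters_give_half(self):
        assert edge_probability(0.0, 0.0, 0.0) == pytest.approx(0.5)

    def test_high_sociality_pair(self):
        # two highly social nodes: logit = -5.68 + 3.48 + 3.41 = 1.21
        expected = 1.0 / (1.0 + np.exp(-1.21))
        assert edge_probability(-5.68, 3.48, 3.41) == pytest.approx(expected, abs=1e-4)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.floats(-30, 30), st.floats(-30, 30), st.floats(-30, 30)
    )
    def test_symmetric_in_socialities_and_in_unit_interval(self, t, ai, aj):
        p = edge_probability(t, ai, aj)
        assert 0.0 <= p <= 1.0
        assert p == edge_probability(t, aj, ai)


class TestLogLikelihood:
    def test_empty_three_node_graph_at_half(self):
        net = network_from_edges([], nodes=["A", "B", "C"])
        p = _params(0.0, a=[0.0] * 3)
        assert log_likelihood(net, p) == pytest.approx(3 * np.log(0.5))

    def test_complete_three_node_graph_symmetric(self, triangle):
        p = _params(0.0, a=[0.0] * 3)
        assert log_likelihood(triangle, p) == pytest.approx(3 * np.log(0.5))

    def test_matches_per_pair_bernoulli_product(self):
        rng = np.random.default_rng(7)
        nodes = ["A", "B", "C", "D"]
        edges = [("A", "B"), ("C", "D"), ("A", "D")]
        net = network_from_edges(edges, nodes=nodes)
        a = rng.standard_normal(4)
        theta = -0.7
        p = _params(theta, a=a)
        expected = 0.0
        for i, j in itertools.combinations(range(4), 2):
            pij = expit(theta + a[i] + a[j])
            x = 1.0 if net.has_edge(nodes[i], nodes[j]) else 0.0
            expected += x * np.log(pij) + (1 - x) * np.log(1 - pij)
        assert log_likelihood(net, p) == pytest.approx(expected, rel=1e-12)

    def test_normalization_over_all_four_node_graphs(self):
        # dyadic independence: likelihoods over all 2^6 graphs sum to 1
        rng = np.random.default_rng(11)
        nodes = ["A", "B", "C", "D"]
        a = rng.standard_normal(4)
        theta = float(rng.standard_normal())
        pairs = list(itertools.combinations(nodes, 2))
        total = 0.0
        for bits in itertools.product([0, 1], repeat=6):
            edges = [pr for pr, b in zip(pairs, bits) if b]
            net = network_from_edges(edges, nodes=nodes)
            total += np.exp(log_likelihood(net, _params(theta, a=a)))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_erdos_renyi_reduction(self):
        # alpha = 0 collapses the model to G(n, p) with p = expit(theta)
        study_edges = [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D"), ("A", "C")]
        net = network_from_edges(study_edges, nodes=list("ABCD"))
        theta = -1.3
        p = expit(theta)
        ll = log_likelihood(net, _params(theta, a=[0.0] * 4))
        expected = net.n_edges * np.log(p) + (net.n_pairs - net.n_edges) * np.log(1 - p)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_directed_network_rejected(self):
        net = network_from_edges([("A", "B")], directed=True)
        with pytest.raises(ValueError, match="undirected"):
            log_likelihood(net, _params(0.0, a=[0.0, 0.0]))


class TestLogPrior:
    def test_zero_theta_is_mode(self):
        at0 = log_prior(_params(0.0, a=[]))
        for t in (-1.0, 0.5, 2.0):
            assert log_prior(_params(t, a=[])) < at0

    def test_matches_term_by_term_density_sum(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(5)
        g = rng.standard_normal(2)
        p = ModelParameters(theta=0.4, gamma=g, a=a,
                            tau_theta=2.0, tau_gamma=0.5, tau_a=1.5)
        h = Hyperparameters()
        expected = norm.logpdf(0.4, scale=2.0**-0.5)
        expected += gamma_dist.logpdf(2.0, h.a0, scale=1 / h.b0)
        expected += norm.logpdf(g, scale=0.5**-0.5).sum()
        expected += gamma_dist.logpdf(0.5, h.a0, scale=1 / h.b0)
        expected += norm.logpdf(a, scale=1.5**-0.5).sum()
        expected += gamma_dist.logpdf(1.5, h.a0, scale=1 / h.b0)
        assert log_prior(p, h) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_precision_rejected(self):
        with pytest.raises(ValueError, match="tau_a"):
            ModelParameters(theta=0.0, gamma=np.array([]), a=np.zeros(2), tau_a=0.0)


class TestLogPosterior:
    def test_is_likelihood_plus_prior(self, triangle):
        p = _params(-0.5, a=[0.1, -0.2, 0.3])
        assert log_posterior(triangle, p) == pytest.approx(
            log_likelihood(triangle, p) + log_prior(p)
        )

    def test_decreases_when_absent_edge_sociality_pushed_up(self):
        # only edge A-B; pushing C's sociality up makes absent edges unlikely
        net = network_from_edges([("A", "B")], nodes=["A", "B", "C"])
        vals = []
        for ac in (0.0, 2.0, 5.0, 10.0):
            p = _params(-1.0, a=[0.0, 0.0, ac])
            vals.append(log_posterior(net, p))
        assert all(v1 > v2 for v1, v2 in zip(vals, vals[1:]))

    def test_invariant_under_node_relabelling(self):
        rng = np.random.default_rng(13)
        nodes = list("ABCDE")
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("A", "E")]
        a = rng.standard_normal(5)
        net = network_from_edges(edges, nodes=nodes)
        lp = log_posterior(net, _params(-0.5, a=a))
        perm = [3, 1, 4, 0, 2]
        relabel = {nodes[i]: nodes[perm[i]] for i in range(5)}
        edges2 = [(relabel[u], relabel[v]) for u, v in edges]
        net2 = network_from_edges(edges2, nodes=nodes)
        a2 = np.empty(5)
        for i in range(5):
            a2[perm[i]] = a[i]
        lp2 = log_posterior(net2, _params(-0.5, a=a2))
        assert lp2 == pytest.approx(lp, rel=1e-12)


class TestDirectedDyads:
    def test_all_zero_parameters_uniform(self):
        d = dyad_probabilities_directed(0, 0, 0, 0, 0, 0)
        assert (d.m, d.a_ij, d.a_ji, d.n) == pytest.approx((0.25,) * 4)

    def test_hand_normalized_exponentials(self):
        # theta=1, phi=2: masses (e^4, e^1, e^1, 1)
        d = dyad_probabilities_directed(1.0, 2.0, 0, 0, 0, 0)
        z = np.exp(4) + 2 * np.e + 1
        assert d.m == pytest.approx(np.exp(4) / z)
        assert d.a_ij == pytest.approx(np.e / z)
        assert d.n == pytest.approx(1 / z)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(*[st.floats(-10, 10) for _ in range(6)])
    def test_four_cells_sum_to_one(self, t, phi, ai, bi, aj, bj):
        d = dyad_probabilities_directed(t, phi, ai, bi, aj, bj)
        assert d.m + d.a_ij + d.a_ji + d.n == pytest.approx(1.0, abs=1e-12)

    def test_zero_reciprocity_factorizes_into_independent_edges(self):
        # phi = 0: dyad law = product of two independent Bernoulli edges
        t, ai, bi, aj, bj = 0.3, 0.5, -0.2, -0.7, 0.9
        d = dyad_probabilities_directed(t, 0.0, ai, bi, aj, bj)
        p_ij = expit(t + ai + bj)  # i -> j
        p_ji = expit(t + aj + bi)  # j -> i
        assert d.m == pytest.approx(p_ij * p_ji, rel=1e-12)
        assert d.a_ij == pytest.approx(p_ij * (1 - p_ji), rel=1e-12)
        assert d.a_ji == pytest.approx((1 - p_ij) * p_ji, rel=1e-12)
        assert d.n == pytest.approx((1 - p_ij) * (1 - p_ji), rel=1e-12)
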