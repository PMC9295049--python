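"""Likelihood machinery: matrix-T density, Laplace marginals, config posterior."""

import numpy as np
import pytest
from scipy.special import logsumexp

from graphmm.graphs import Graph, Partition, make_edges
from graphmm.model import (Hyperparams, TwoGroupData, config_log_prior,
                           expand_block_means, laplace_log_marginal, local_fdr,
                           log_density_given_means, posterior_over_configs,
                           sufficient_stats)
from graphmm.graphs import enumerate_graph_respecting_partitions
from helpers_oracles import invgamma_group_marginal, is_config_marginal


def _hyper(n, **kw):
    base = dict(mu0=0.0, tau2=1.0, delta0=0.0, sigma2=1.0, df=n + 2,
                A=np.eye(n), B=np.eye(n), p0=0.5)
    base.update(kw)
    return Hyperparams(**base)


class TestSufficientStats:
    def test_identical_columns_give_zero_covariance(self):
        X = np.tile([[1.0], [2.0]], (1, 4))
        stats = sufficient_stats(TwoGroupData(X, X))
        assert np.allclose(stats.S1, 0) and np.allclose(stats.T1, 0)

    def test_hand_computed_scalar_case(self):
        stats = sufficient_stats(TwoGroupData([[1.0, 2.0, 3.0]], [[0.0, 0.0]]))
        assert stats.xbar[0] == 2.0
        assert stats.S1[0, 0] == 1.0

    def test_matches_elementwise_brute_force(self, rng):
        X = rng.normal(size=(3, 5))
        Y = rng.normal(size=(3, 4))
        stats = sufficient_stats(TwoGroupData(X, Y))
        S = np.zeros((3, 3))
        xb = X.mean(axis=1)
        for m in range(5):
            d = X[:, m] - xb
            S += np.outer(d, d)
        assert np.allclose(stats.S1, S / 4)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            TwoGroupData([[1.0]], [[1.0, 2.0]])


class TestExpandBlockMeans:
    def test_single_null_block(self):
        muX, muY = expand_block_means(Partition(((0, 1, 2),)), (0,), (2.0,))
        assert np.allclose(muX, 2.0) and np.allclose(muY, 2.0)

    def test_shifted_and_null_blocks(self):
        part = Partition(((0, 1), (2,)))
        muX, muY = expand_block_means(part, (1, 0), (0.0, 1.0), (3.0,))
        assert np.allclose(muX, [0, 0, 1])
        assert np.allclose(muY, [3, 3, 1])

    def test_all_singletons_unconstrained(self):
        part = Partition(((0,), (1,), (2,)))
        muX, muY = expand_block_means(part, (1, 1, 1), (1.0, 2.0, 3.0),
                                      (0.5, -0.5, 1.5))
        assert np.allclose(muX, [1, 2, 3])
        assert np.allclose(muY, [1.5, 1.5, 4.5])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            expand_block_means(Partition(((0, 1),)), (0, 1), (1.0,))


class TestLogDensity:
    def test_matches_inverse_gamma_quadrature_n1(self):
        X = np.array([[0.3, 1.1]])
        Y = np.array([[-0.5, 0.2]])
        stats = sufficient_stats(TwoGroupData(X, Y))
        hyper = _hyper(1, df=3.0)
        val = log_density_given_means(stats, [0.4], [-0.1], hyper)
        oracle = (invgamma_group_marginal(X[0], 0.4, 1.0, 3.0)
                  + invgamma_group_marginal(Y[0], -0.1, 1.0, 3.0))
        assert abs(val - oracle) < 1e-8

    def test_maximized_at_data_means(self, rng):
        X = rng.normal(size=(2, 6))
        Y = rng.normal(size=(2, 6))
        stats = sufficient_stats(TwoGroupData(X, Y))
        hyper = _hyper(2)
        best = log_density_given_means(stats, stats.xbar, stats.ybar, hyper)
        for _ in range(20):
            other = log_density_given_means(
                stats, stats.xbar + rng.normal(scale=0.5, size=2),
                stats.ybar + rng.normal(scale=0.5, size=2), hyper)
            assert other <= best + 1e-12

    def test_group_swap_symmetry(self, rng):
        X = rng.normal(size=(2, 5))
        Y = rng.normal(size=(2, 5))
        hyper = _hyper(2)
        muX, muY = np.array([0.1, -0.2]), np.array([0.3, 0.0])
        a = log_density_given_means(sufficient_stats(TwoGroupData(X, Y)), muX, muY, hyper)
        b = log_density_given_means(sufficient_stats(TwoGroupData(Y, X)), muY, muX, hyper)
        assert np.isclose(a, b)

    def test_rejects_non_pd_scale(self):
        with pytest.raises(ValueError):
            _hyper(2, A=np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestLaplace:
    def test_single_block_matches_quadrature(self, rng):
        from scipy import integrate
        from scipy.stats import norm

        X = rng.normal(0.5, 1.0, size=(2, 4))
        Y = rng.normal(0.5, 1.0, size=(2, 4))
        stats = sufficient_stats(TwoGroupData(X, Y))
        hyper = _hyper(2, mu0=0.2, tau2=1.5, df=5.0)
        lap = laplace_log_marginal(stats, Partition(((0, 1),)), (0,), hyper)

        def f(phi):
            return np.exp(log_density_given_means(
                stats, np.array([phi, phi]), np.array([phi, phi]), hyper)
            ) * norm.pdf(phi, 0.2, np.sqrt(1.5))

        quad = np.log(integrate.quad(f, -15, 15, limit=300)[0])
        assert abs(lap - quad) / abs(quad) < 0.02

    def test_vertex_relabel_invariance(self, rng):
        X = rng.normal(size=(3, 5))
        Y = rng.normal(size=(3, 5))
        hyper = _hyper(3)
        part = Partition(((0, 1), (2,)))
        stats = sufficient_stats(TwoGroupData(X, Y))
        val = laplace_log_marginal(stats, part, (1, 0), hyper)
        perm = [2, 0, 1]  # vertex v -> perm[v]
        Xp, Yp = np.empty_like(X), np.empty_like(Y)
        Xp[perm], Yp[perm] = X, Y
        part_p = Partition(tuple(tuple(perm[v] for v in b) for b in part.blocks))
        # the shifted block (0,1) maps to {2,0}; delta follows canonical order
        delta_p = tuple(1 if set(b) == {0, 2} else 0 for b in part_p.blocks)
        stats_p = sufficient_stats(TwoGroupData(Xp, Yp))
        val_p = laplace_log_marginal(stats_p, part_p, delta_p, hyper)
        assert np.isclose(val, val_p, rtol=1e-9)

    def test_small_tau_pins_means_at_mu0(self, rng):
        X = rng.normal(size=(2, 5))
        Y = rng.normal(size=(2, 5))
        stats = sufficient_stats(TwoGroupData(X, Y))
        mu0 = 0.3
        hyper = _hyper(2, mu0=mu0, tau2=1e-10)
        lap = laplace_log_marginal(stats, Partition(((0, 1),)), (0,), hyper)
        pinned = log_density_given_means(
            stats, np.full(2, mu0), np.full(2, mu0), hyper)
        assert abs(lap - pinned) < 1e-3 * abs(pinned)


class TestConfigPrior:
    def test_half_prior_value(self):
        part = Partition(((0,), (1, 2)))
        val = config_log_prior(part, (0, 1), 0.5, 1434)
        assert np.isclose(val, -np.log(1434) - 2 * np.log(2))

    def test_p0_limits(self):
        part = Partition(((0, 1),))
        assert config_log_prior(part, (1,), 1.0, 4) == -np.inf
        assert config_log_prior(part, (0,), 1.0, 4) == -np.log(4)
        assert config_log_prior(part, (0,), 0.0, 4) == -np.inf

    @pytest.mark.parametrize("graph_fixture", ["path3", "lattice33"])
    def test_prior_sums_to_one_over_all_configs(self, graph_fixture, request):
        from itertools import product

        graph = request.getfixturevalue(graph_fixture)
        parts = enumerate_graph_respecting_partitions(graph)
        total = []
        for part in parts:
            for delta in product((0, 1), repeat=part.K):
                total.append(config_log_prior(part, delta, 0.3, len(parts)))
        assert np.isclose(logsumexp(np.array(total)), 0.0, atol=1e-10)


class TestPosterior:
    def test_weights_normalized_and_bounded(self, path3, rng):
        X = rng.normal(size=(3, 4))
        Y = rng.normal(size=(3, 4))
        post = posterior_over_configs(TwoGroupData(X, Y), path3, _hyper(3))
        assert np.isclose(logsumexp(post.log_weights), 0.0, atol=1e-10)
        for v in range(3):
            assert 0.0 <= local_fdr(post, v) <= 1.0

    def test_strong_null_prior_dominates(self, path3, rng):
        X = rng.normal(size=(3, 4))
        Y = rng.normal(size=(3, 4)) + 3.0
        post = posterior_over_configs(TwoGroupData(X, Y), path3,
                                      _hyper(3, p0=1 - 1e-12))
        assert all(local_fdr(post, v) > 0.999 for v in range(3))

    def test_map_recovers_generative_blocking(self, path3):
        """With strong block signal, the MAP partition finds the split."""
        rng = np.random.default_rng(7)
        truth = Partition(((0, 1), (2,)))
        hits = 0
        for _ in range(50):
            phi = np.array([0.0, 2.5])
            labels = truth.labels()
            X = phi[labels][:, None] + rng.normal(scale=0.1, size=(3, 6))
            Y = phi[labels][:, None] + rng.normal(scale=0.1, size=(3, 6))
            Y[labels == 0] += 1.5
            post = posterior_over_configs(
                TwoGroupData(X, Y), path3,
                _hyper(3, tau2=2.0, sigma2=1.0, A=0.05 * np.eye(3), B=0.05 * np.eye(3)))
            best = post.configs[int(np.argmax(post.log_weights))]
            hits += best.partition == truth
        assert hits >= 45

    def test_local_fdr_matches_double_loop_sum(self, rng):
        """Independently coded summation over the two-vertex config table."""
        g2 = Graph(n=2, edges=make_edges([(0, 1)]))
        X = rng.normal(size=(2, 4))
        Y = rng.normal(size=(2, 4))
        Y[0] += 1.0
        hyper = _hyper(2)
        post = posterior_over_configs(TwoGroupData(X, Y), g2, hyper)
        stats = sufficient_stats(TwoGroupData(X, Y))
        parts = enumerate_graph_respecting_partitions(g2)
        from itertools import product

        raw = {}
        for part in parts:
            for delta in product((0, 1), repeat=part.K):
                lp = config_log_prior(part, delta, hyper.p0, len(parts))
                lm = laplace_log_marginal(stats, part, delta, hyper)
                raw[(part.blocks, delta)] = lp + lm
        z = logsumexp(np.array(list(raw.values())))
        for v in range(2):
            terms = []
            for (blocks, delta), lw in raw.items():
                k = next(i for i, b in enumerate(blocks) if v in b)
                if delta[k] == 0:
                    terms.append(lw)
            oracle = np.exp(logsumexp(np.array(terms)) - z)
            assert np.isclose(local_fdr(post, v), oracle, atol=1e-12)

    def test_separation_monotonicity_single_vertex(self):
        """Growing group separation never raises the local FDR."""
        g1 = Graph(n=1, edges=frozenset())
        hyper = _hyper(1)
        prev = None
        for shift in np.linspace(0, 3, 7):
            X = np.array([[-0.1, 0.0, 0.1, 0.0]])
            Y = X + shift
            post = posterior_over_configs(TwoGroupData(X, Y), g1, hyper)
            l = local_fdr(post, 0)
            if prev is not None:
                assert l <= prev + 1e-12
            prev = l

    def test_permutation_equivariance(self, path3, rng):
        X = rng.normal(size=(3, 5))
        Y = rng.normal(size=(3, 5))
        Y[0] += 1.2
        hyper = _hyper(3)
        post = posterior_over_configs(TwoGroupData(X, Y), path3, hyper)
        perm = [2, 1, 0]  # an automorphism of the path
        Xp, Yp = np.empty_like(X), np.empty_like(Y)
        Xp[perm], Yp[perm] = X, Y
        post_p = posterior_over_configs(TwoGroupData(Xp, Yp), path3, hyper)
        for v in range(3):
            assert np.isclose(local_fdr(post, v), local_fdr(post_p, perm[v]),
                              atol=1e-9)
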