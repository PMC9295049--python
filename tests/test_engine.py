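"""Whole-lattice engine: consistency, discovery lists, rates, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graphmm.engine import (EvalResult, controlled_fdr, discovery_list,
                            empirical_fdr_tpr, run_graphmm, significant_clusters,
                            storey_qvalues, tpr_at_empirical_fdr,
                            ttest_bh_baseline)
from graphmm.graphs import build_lattice_graph, local_subgraph
from graphmm.hyperparams import estimate_hyperparams
from graphmm.model import (Hyperparams, TwoGroupData, local_fdr,
                           posterior_over_configs)
from graphmm.simulate import ScenarioSpec, simulate_scenario


@pytest.fixture(scope="module")
def small_run():
    spec = ScenarioSpec(dims=(10, 10), block_size_law=("uniform", 12, 14),
                        shift_fraction=0.3, shift_magnitude=0.8, seed=3)
    data, truth = simulate_scenario(spec)
    result = run_graphmm(data, spec.dims, neighborhood="star2d")
    return data, truth, result


def test_single_vertex_lattice_reduces_to_conjugate_test(rng):
    data = TwoGroupData(rng.normal(size=(1, 6)), rng.normal(size=(1, 6)) + 1.0)
    hyper = Hyperparams(mu0=0, tau2=1, delta0=0, sigma2=1, df=3,
                        A=[[1.0]], B=[[1.0]], p0=0.7)
    res = run_graphmm(data, (1, 1), neighborhood="star2d", hyper=hyper)
    graph = build_lattice_graph((1, 1))
    post = posterior_over_configs(data, graph, hyper)
    assert np.isclose(res.lfdr[0], local_fdr(post, 0), atol=1e-12)


def test_engine_matches_single_graph_api(small_run):
    """Batched whole-lattice scores equal per-vertex exhaustive posteriors."""
    data, _, result = small_run
    graph = build_lattice_graph((10, 10))
    for v in (0, 5, 44, 99):  # corner, edge, interior, corner
        sub = local_subgraph(graph, v, "star2d")
        hy = result.hyper.subset(sub.slots)
        post = posterior_over_configs(data.restrict(sub.vertices), sub.graph, hy)
        assert np.isclose(result.lfdr[v], local_fdr(post, sub.center), atol=1e-9)


def test_signal_blocks_score_lower(small_run):
    _, truth, result = small_run
    assert result.lfdr[~truth.is_null].mean() < result.lfdr[truth.is_null].mean()
    assert not result.failed.any()


def test_lattice3x3_neighborhood_small_lattice():
    spec = ScenarioSpec(dims=(4, 2), block_size_law=("uniform", 2, 4),
                        shift_fraction=0.5, shift_magnitude=1.5, seed=12)
    data, truth = simulate_scenario(spec)
    res = run_graphmm(data, spec.dims, neighborhood="lattice3x3")
    assert res.lfdr.shape == (8,)
    assert ((res.lfdr >= 0) & (res.lfdr <= 1)).all()
    if (~truth.is_null).any() and truth.is_null.any():
        assert res.lfdr[~truth.is_null].mean() <= res.lfdr[truth.is_null].mean()


def test_discovery_list_thresholds(small_run):
    _, _, result = small_run
    assert discovery_list(result, 1.0).size == result.lfdr.size
    assert discovery_list(result, 0.0).size == (result.lfdr == 0).sum()
    l1 = set(discovery_list(result, 0.02).tolist())
    l2 = set(discovery_list(result, 0.1).tolist())
    assert l1 <= l2
    lst = discovery_list(result, 0.5)
    assert np.all(np.diff(result.lfdr[lst]) >= 0)


def test_controlled_fdr_values(small_run):
    _, _, result = small_run
    lst = discovery_list(result, 0.2)
    assert np.isclose(controlled_fdr(result, lst),
                      sum(result.lfdr[v] for v in lst) / lst.size)
    assert controlled_fdr(result, lst[:1]) == result.lfdr[lst[0]]
    with pytest.raises(ValueError):
        controlled_fdr(result, np.array([], dtype=int))


def test_empirical_fdr_tpr_counting():
    is_null = np.array([True, True, False, False, True])
    only_nulls = empirical_fdr_tpr(np.array([0, 1]), is_null)
    assert only_nulls.empirical_fdr == 1.0 and only_nulls.tpr == 0.0
    exact = empirical_fdr_tpr(np.array([2, 3]), is_null)
    assert exact.empirical_fdr == 0.0 and exact.tpr == 1.0
    mixed = empirical_fdr_tpr(np.array([0, 2, 3]), is_null)
    assert np.isclose(mixed.empirical_fdr, 1 / 3) and mixed.tpr == 1.0
    empty = empirical_fdr_tpr(np.array([], dtype=int), is_null)
    assert empty.empty and empty.empirical_fdr == 0.0


def test_tpr_at_matched_fdr():
    scores = np.array([0.01, 0.02, 0.5, 0.6, 0.9])
    is_null = np.array([False, False, True, False, True])
    assert tpr_at_empirical_fdr(scores, is_null, 0.0) == 2 / 3
    assert tpr_at_empirical_fdr(scores, is_null, 0.34) == 1.0


class TestBaselines:
    def test_bh_null_rejects_rarely(self):
        rng = np.random.default_rng(17)
        data = TwoGroupData(rng.normal(size=(500, 15)), rng.normal(size=(500, 15)))
        _, _, reject = ttest_bh_baseline(data, 0.05)
        assert reject.mean() <= 0.01

    def test_bh_single_vertex_equals_raw(self, rng):
        data = TwoGroupData(rng.normal(size=(1, 5)), rng.normal(size=(1, 5)))
        p, adj, _ = ttest_bh_baseline(data)
        assert np.isclose(p[0], adj[0])

    def test_bh_adjustment_monotone(self, rng):
        data = TwoGroupData(rng.normal(size=(50, 8)), rng.normal(size=(50, 8)))
        p, adj, _ = ttest_bh_baseline(data)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_storey_single_pvalue(self):
        q = storey_qvalues(np.array([0.04]), p0=0.9)
        assert np.isclose(q[0], 0.9 * 0.04)

    def test_storey_monotone_and_bh_relation(self, rng):
        p = rng.random(200)
        q = storey_qvalues(p, p0=0.8)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        # q-values are p0 times the BH-adjusted values
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, np.minimum(0.8 * adj, 1.0))


def test_significant_clusters(small_run):
    _, _, result = small_run
    comps = significant_clusters(result, 0.5)
    total = sum(len(c) for c in comps)
    assert total == discovery_list(result, 0.5).size
    assert all(len(c) >= 1 for c in comps)


def test_mismatched_hyper_window_rejected(rng):
    data = TwoGroupData(rng.normal(size=(4, 4)), rng.normal(size=(4, 4)))
    hyper = Hyperparams(mu0=0, tau2=1, delta0=0, sigma2=1, df=5,
                        A=np.eye(3), B=np.eye(3), p0=0.5)
    with pytest.raises(ValueError):
        run_graphmm(data, (2, 2), neighborhood="star2d", hyper=hyper)


@settings(max_examples=20, deadline=None)
@given(st.floats(min_value=0.0, max_value=1.0),
       st.floats(min_value=0.0, max_value=1.0))
def test_discovery_lists_nested_property(c1, c2):
    lfdr = np.linspace(0, 1, 37) ** 2
    graph = build_lattice_graph((37, 1))
    hyper = Hyperparams(mu0=0, tau2=1, delta0=0, sigma2=1, df=7,
                        A=np.eye(5), B=np.eye(5), p0=0.5)
    from graphmm.engine import LfdrResult

    res = LfdrResult(lfdr=lfdr, neighborhood="star2d", hyper=hyper,
                     graph=graph, failed=np.zeros(37, bool))
    lo, hi = sorted((c1, c2))
    assert set(discovery_list(res, lo).tolist()) <= set(discovery_list(res, hi).tolist())
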