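"""Whole-lattice driver: per-vertex local FDRs, discovery lists, baselines.

For every vertex the engine extracts the local subgraph, restricts the data
and the global scale matrices to it, runs the exhaustive mixture over
(partition, shift) configurations, and keeps the posterior null probability
of the center vertex only.  Vertices sharing a window shape are processed
as one batch; the arithmetic is identical to the single-graph API, and the
result does not depend on the order in which vertices are visited.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import _laplace
from .graphs import Graph, build_lattice_graph, enumerate_graph_respecting_partitions, local_subgraph
from .hyperparams import EstimatorConfig, estimate_hyperparams, estimate_p0, welch_pvalues
from .model import Hyperparams, TwoGroupData, config_log_prior, _all_deltas

__all__ = [
    "LfdrResult",
    "EvalResult",
    "run_graphmm",
    "discovery_list",
    "controlled_fdr",
    "empirical_fdr_tpr",
    "tpr_at_empirical_fdr",
    "ttest_bh_baseline",
    "storey_qvalues",
    "significant_clusters",
]


@dataclass
class LfdrResult:
    """Per-vertex local FDRs from a whole-lattice run."""

    lfdr: np.ndarray
    neighborhood: str
    hyper: Hyperparams
    graph: Graph
    failed: np.ndarray
    runtime_s: float = 0.0

    def __post_init__(self):
        if ((self.lfdr < 0) | (self.lfdr > 1)).any():
            raise ValueError("local FDRs must lie in [0, 1]")


@dataclass
class EvalResult:
    """Error/detection rates of a discovery list."""

    controlled_fdr: float
    list_size: int
    empirical_fdr: float | None = None
    tpr: float | None = None
    empty: bool = False


def _as_graph(graph_or_dims) -> Graph:
    if isinstance(graph_or_dims, Graph):
        return graph_or_dims
    return build_lattice_graph(graph_or_dims)


def run_graphmm(
    data: TwoGroupData,
    graph_or_dims,
    neighborhood: str = "star2d",
    hyper: Hyperparams | None = None,
    estimator_config: EstimatorConfig | None = None,
    cap: int = 12,
) -> LfdrResult:
    """Score every vertex of a lattice with its local-subgraph mixture lfdr.

    ``hyper`` defaults to the empirical-Bayes estimates from the whole
    lattice; its A/B matrices must be sized to the full window of
    ``neighborhood`` and are subset to clipped border windows.  Vertices
    whose local computation fails are reported conservatively with l_v = 1.
    """
    t0 = time.perf_counter()
    graph = _as_graph(graph_or_dims)
    if data.n_vertices != graph.n:
        raise ValueError("data rows must match lattice order")
    if hyper is None:
        hyper = estimate_hyperparams(data, graph, neighborhood, estimator_config).hyper
    # group vertices by window shape (present slots determine the subgraph)
    groups: dict[tuple, list[tuple[int, tuple[int, ...]]]] = {}
    subs = {}
    for v in range(graph.n):
        sub = local_subgraph(graph, v, neighborhood)
        groups.setdefault(sub.slots, []).append((v, sub.vertices))
        subs[sub.slots] = sub

    max_slot = max(max(s) for s in groups)
    if hyper.window_order <= max_slot:
        raise ValueError(
            f"hyper A/B are {hyper.window_order}x{hyper.window_order} but the "
            f"{neighborhood} windows use slots up to {max_slot}")

    lfdr = np.full(graph.n, np.nan)
    failed = np.zeros(graph.n, dtype=bool)
    for slots, members in groups.items():
        sub = subs[slots]
        centers = np.array([v for v, _ in members])
        idx = np.array([list(ids) for _, ids in members])        # (V, n)
        try:
            parts = enumerate_graph_respecting_partitions(sub.graph, cap=cap)
            hy = hyper.subset(slots) if len(slots) < hyper.window_order else hyper
            local = _laplace.build_local_batch(
                data.X[idx], data.Y[idx], hy.A, hy.B, hy.df)
            logpost = []
            is_null_center = []
            for part in parts:
                labels = part.labels()
                pq = _laplace.partition_quantities(local, labels, part.K)
                k_center = int(labels[sub.center])
                for delta, act in _all_deltas(part.K):
                    lp = config_log_prior(part, delta, hy.p0, len(parts))
                    if lp == -np.inf:
                        continue
                    lm = _laplace.laplace_config_log_marginal(
                        local, pq, act, hy.mu0, hy.tau2, hy.delta0, hy.sigma2)
                    logpost.append(lp + lm)
                    is_null_center.append(delta[k_center] == 0)
            logpost = np.asarray(logpost)                         # (n_cfg, V)
            null_mask = np.asarray(is_null_center)
            logZ = logsumexp(logpost, axis=0)
            lnum = logsumexp(logpost[null_mask], axis=0)
            lv = np.exp(np.clip(lnum - logZ, -np.inf, 0.0))
            ok = np.isfinite(lv)
            lfdr[centers[ok]] = lv[ok]
            if (~ok).any():
                raise FloatingPointError("non-finite local FDR in batch")
        except Exception as err:  # failed vertices are conservative, never dropped
            bad = centers[~np.isfinite(lfdr[centers])]
            warnings.warn(
                f"local model failed for {bad.size} vertices (shape {slots}): {err}; "
                "reporting l_v = 1", RuntimeWarning, stacklevel=2)
            lfdr[bad] = 1.0
            failed[bad] = True
    return LfdrResult(lfdr=lfdr, neighborhood=neighborhood, hyper=hyper,
                      graph=graph, failed=failed,
                      runtime_s=time.perf_counter() - t0)


def discovery_list(result: LfdrResult, c: float) -> np.ndarray:
    """Vertices with l_v <= c, sorted by l_v ascending (ties by vertex id)."""
    if not (0.0 <= c <= 1.0):
        raise ValueError("threshold c must lie in [0, 1]")
    hits = np.flatnonzero(result.lfdr <= c)
    order = np.lexsort((hits, result.lfdr[hits]))
    return hits[order]


def controlled_fdr(result: LfdrResult, vertices: np.ndarray) -> float:
    """Mean local FDR over a list: the data-computable bound on its FDR."""
    vertices = np.asarray(vertices)
    if vertices.size == 0:
        raise ValueError("controlled FDR is undefined for an empty list")
    return float(result.lfdr[vertices].mean())


def empirical_fdr_tpr(vertices: np.ndarray, is_null: np.ndarray) -> EvalResult:
    """Truth-based error rates of a list (synthetic runs only)."""
    vertices = np.asarray(vertices, dtype=int)
    is_null = np.asarray(is_null, dtype=bool)
    n_nonnull = int((~is_null).sum())
    if vertices.size == 0:
        return EvalResult(controlled_fdr=np.nan, list_size=0, empirical_fdr=0.0,
                          tpr=0.0, empty=True)
    n_false = int(is_null[vertices].sum())
    fdr = n_false / vertices.size
    tpr = (vertices.size - n_false) / n_nonnull if n_nonnull else 0.0
    return EvalResult(controlled_fdr=np.nan, list_size=int(vertices.size),
                      empirical_fdr=float(fdr), tpr=float(tpr))


def tpr_at_empirical_fdr(scores: np.ndarray, is_null: np.ndarray, level: float) -> float:
    """TPR of the largest score-ranked prefix whose empirical FDR <= level.

    Scores are ranked ascending (small = more significant), so the same
    helper serves lfdr scores and p-values alike.
    """
    scores = np.asarray(scores, dtype=float)
    is_null = np.asarray(is_null, dtype=bool)
    order = np.lexsort((np.arange(scores.size), scores))
    fdp = np.cumsum(is_null[order]) / np.arange(1, scores.size + 1)
    ok = np.flatnonzero(fdp <= level)
    if ok.size == 0:
        return 0.0
    m = ok[-1] + 1
    n_nonnull = int((~is_null).sum())
    hits = int((~is_null[order[:m]]).sum())
    return hits / n_nonnull if n_nonnull else 0.0


def ttest_bh_baseline(data: TwoGroupData, alpha: float = 0.05):
    """Per-vertex Welch t-tests with Benjamini-Hochberg step-up adjustment.

    Returns (raw p-values, BH-adjusted p-values, rejection mask at alpha).
    """
    pvals = welch_pvalues(data)
    reject, adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pvals, adj, reject


def storey_qvalues(pvalues: np.ndarray, p0: float | None = None) -> np.ndarray:
    """Storey q-values: q_i = min over p_j >= p_i of p0 * n * p_j / rank_j."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if p0 is None:
        p0 = estimate_p0(p)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1] * p0
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def significant_clusters(result: LfdrResult, c: float = 0.05) -> list[set[int]]:
    """Connected components of the discovery mask at threshold c (post hoc)."""
    import networkx as nx

    hits = set(discovery_list(result, c).tolist())
    sub = result.graph.to_networkx().subgraph(hits)
    comps = [set(cc) for cc in nx.connected_components(sub)]
    comps.sort(key=len, reverse=True)
    return comps
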