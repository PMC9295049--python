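"""Mixture model over graph-respecting partitions and block-shift indicators.

The sampling model is multivariate Gaussian per group with unknown
covariances carrying conjugate inverse-Wishart priors, integrated out
analytically to a matrix-T form.  Block base-means phi_k and (for shifted
blocks) contrasts delta_k carry Gaussian priors and are marginalized with a
Laplace approximation.  The discrete posterior over (partition, Delta)
pairs yields, for each vertex, the local false-discovery rate

    l_v = P(mu_X,v = mu_Y,v | X, Y)
        = sum over configs of  w(config) * 1[v's block is unshifted].

All mixture arithmetic is done in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from . import _laplace
from .graphs import Graph, Partition, enumerate_graph_respecting_partitions

__all__ = [
    "TwoGroupData",
    "SufficientStats",
    "Hyperparams",
    "ModelConfig",
    "ConfigPosterior",
    "sufficient_stats",
    "expand_block_means",
    "log_density_given_means",
    "laplace_log_marginal",
    "config_log_prior",
    "posterior_over_configs",
    "local_fdr",
]


@dataclass
class TwoGroupData:
    """Two-group measurements: X is N x M_X (group 1), Y is N x M_Y (group 2)."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2D (vertices x samples)")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of vertices")
        if self.X.shape[1] < 2 or self.Y.shape[1] < 2:
            raise ValueError("each group needs at least 2 samples")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("missing or non-finite values are not supported")

    @property
    def n_vertices(self) -> int:
        return self.X.shape[0]

    @property
    def M_X(self) -> int:
        return self.X.shape[1]

    @property
    def M_Y(self) -> int:
        return self.Y.shape[1]

    def restrict(self, vertices: Sequence[int]) -> "TwoGroupData":
        idx = list(vertices)
        return TwoGroupData(self.X[idx], self.Y[idx])


@dataclass
class SufficientStats:
    """Column means and unbiased sample covariances of the two groups."""

    xbar: np.ndarray
    ybar: np.ndarray
    S1: np.ndarray
    T1: np.ndarray
    M_X: int
    M_Y: int


def sufficient_stats(data: TwoGroupData) -> SufficientStats:
    X, Y = data.X, data.Y
    xbar = X.mean(axis=1)
    ybar = Y.mean(axis=1)
    Xc = X - xbar[:, None]
    Yc = Y - ybar[:, None]
    S1 = Xc @ Xc.T / (data.M_X - 1)
    T1 = Yc @ Yc.T / (data.M_Y - 1)
    return SufficientStats(xbar=xbar, ybar=ybar, S1=S1, T1=T1,
                           M_X=data.M_X, M_Y=data.M_Y)


@dataclass
class Hyperparams:
    """Global hyperparameters of the mixture model.

    mu0/tau2 parameterize the Gaussian prior on block base-means, delta0 and
    sigma2 the prior on block shifts, (A, df) and (B, df) the inverse-Wishart
    priors on the group covariances (A, B sized to the full local window),
    and p0 is the per-block prior null probability.
    """

    mu0: float
    tau2: float
    delta0: float
    sigma2: float
    df: float
    A: np.ndarray
    B: np.ndarray
    p0: float

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if self.tau2 <= 0 or self.sigma2 <= 0:
            raise ValueError("tau2 and sigma2 must be positive")
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must lie in [0, 1]")
        n = self.A.shape[0]
        if self.A.shape != (n, n) or self.B.shape != (n, n):
            raise ValueError("A and B must be square and of equal size")
        if self.df <= n + 1:
            raise ValueError("df must exceed the scale-matrix order plus one")
        for name, mat in (("A", self.A), ("B", self.B)):
            try:
                np.linalg.cholesky(mat)
            except np.linalg.LinAlgError as err:
                raise ValueError(f"{name} must be positive definite") from err

    @property
    def window_order(self) -> int:
        return self.A.shape[0]

    def subset(self, idx: Sequence[int]) -> "Hyperparams":
        """Principal-submatrix restriction of A and B to a clipped window."""
        idx = list(idx)
        return Hyperparams(
            mu0=self.mu0, tau2=self.tau2, delta0=self.delta0,
            sigma2=self.sigma2, df=self.df,
            A=self.A[np.ix_(idx, idx)], B=self.B[np.ix_(idx, idx)],
            p0=self.p0,
        )


@dataclass
class ModelConfig:
    """One discrete mixture component: a partition with shift indicators."""

    partition: Partition
    delta: tuple[int, ...]
    log_prior: float
    log_marginal: float


@dataclass
class ConfigPosterior:
    """Normalized discrete posterior over (partition, Delta) configurations."""

    graph: Graph
    configs: list[ModelConfig]
    log_weights: np.ndarray

    def to_frame(self):
        import pandas as pd

        rows = []
        for cfg, lw in zip(self.configs, self.log_weights):
            pid = ";".join(",".join(map(str, b)) for b in cfg.partition.blocks)
            mask = sum(d << k for k, d in enumerate(cfg.delta))
            rows.append((pid, mask, lw))
        return pd.DataFrame(rows, columns=["partition", "delta_mask", "log_weight"])


def expand_block_means(
    partition: Partition,
    delta: Sequence[int],
    phi: Sequence[float],
    dvals: Sequence[float] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Expand block-level parameters to per-vertex mean vectors.

    ``dvals`` lists the shift values of the active blocks (Delta_k = 1), in
    block order.  Vertices in unshifted blocks have equal means in both
    groups.
    """
    K = partition.K
    delta = tuple(int(d) for d in delta)
    phi = np.asarray(phi, dtype=float)
    if len(delta) != K or phi.shape != (K,):
        raise ValueError("delta and phi must have one entry per block")
    act = [k for k in range(K) if delta[k]]
    dvals = np.asarray(dvals, dtype=float)
    if dvals.shape != (len(act),):
        raise ValueError("dvals must have one entry per active block")
    nu = phi.copy()
    nu[act] += dvals
    labels = partition.labels()
    return phi[labels], nu[labels]


def _prepared_stats_batch(stats: SufficientStats, hyper: Hyperparams) -> _laplace.LocalBatch:
    """Wrap SufficientStats as a batch of one for the Laplace machinery."""
    n = stats.xbar.shape[0]
    A0 = hyper.A + (stats.M_X - 1) * stats.S1
    B0 = hyper.B + (stats.M_Y - 1) * stats.T1
    cholA, A0b = _laplace.guarded_cholesky(A0[None], "A + (M_X-1) S1")
    cholB, B0b = _laplace.guarded_cholesky(B0[None], "B + (M_Y-1) T1")
    logdetA0 = _laplace._chol_logdet(cholA)
    logdetB0 = _laplace._chol_logdet(cholB)
    aX = 0.5 * (hyper.df + stats.M_X)
    aY = 0.5 * (hyper.df + stats.M_Y)
    const = (
        _laplace.log_density_constant(n, stats.M_X, stats.M_Y, hyper.df)
        + 0.5 * hyper.df * (np.linalg.slogdet(hyper.A)[1] + np.linalg.slogdet(hyper.B)[1])
        - aX * logdetA0
        - aY * logdetB0
    )
    return _laplace.LocalBatch(
        xbar=stats.xbar[None], ybar=stats.ybar[None],
        Ainv=np.linalg.inv(A0b), Binv=np.linalg.inv(B0b),
        const_f=const, MX=stats.M_X, MY=stats.M_Y, df=hyper.df,
    )


def log_density_given_means(
    stats: SufficientStats,
    muX: np.ndarray,
    muY: np.ndarray,
    hyper: Hyperparams,
) -> float:
    """Absolute log density f(X, Y | mu_X, mu_Y) with covariances integrated out.

    The value is C * |A|^(df/2) |B|^(df/2) / (|A~|^((df+M_X)/2) |B~|^((df+M_Y)/2))
    on the log scale, where A~ = A + (M_X-1) S1 + M_X (xbar-mu_X)(xbar-mu_X)'
    and B~ analogously, and C is the multivariate-gamma normalizing constant,
    so unit tests can check it as a genuine density of the data.
    """
    muX = np.asarray(muX, dtype=float)
    muY = np.asarray(muY, dtype=float)
    n = stats.xbar.shape[0]
    if muX.shape != (n,) or muY.shape != (n,):
        raise ValueError("mean vectors must match the number of vertices")
    A0 = hyper.A + (stats.M_X - 1) * stats.S1
    B0 = hyper.B + (stats.M_Y - 1) * stats.T1
    for name, mat in (("A + (M_X-1)S1", A0), ("B + (M_Y-1)T1", B0)):
        try:
            np.linalg.cholesky(mat)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"{name} is not positive definite; regularize A/B (e.g. add "
                "a small multiple of the identity)") from err
    dx = stats.xbar - muX
    dy = stats.ybar - muY
    At = A0 + stats.M_X * np.outer(dx, dx)
    Bt = B0 + stats.M_Y * np.outer(dy, dy)
    aX = 0.5 * (hyper.df + stats.M_X)
    aY = 0.5 * (hyper.df + stats.M_Y)
    return float(
        _laplace.log_density_constant(n, stats.M_X, stats.M_Y, hyper.df)
        + 0.5 * hyper.df * (np.linalg.slogdet(hyper.A)[1] + np.linalg.slogdet(hyper.B)[1])
        - aX * np.linalg.slogdet(At)[1]
        - aY * np.linalg.slogdet(Bt)[1]
    )


def laplace_log_marginal(
    stats: SufficientStats,
    partition: Partition,
    delta: Sequence[int],
    hyper: Hyperparams,
) -> float:
    """Log marginal predictive density of one (partition, Delta) configuration.

    Integrates the free block means (and active shifts) out of
    ``log_density_given_means`` plus their Gaussian priors, by Laplace
    approximation around the Newton mode.
    """
    delta = tuple(int(d) for d in delta)
    if len(delta) != partition.K:
        raise ValueError("delta must have one indicator per block")
    local = _prepared_stats_batch(stats, hyper)
    labels = partition.labels()
    pq = _laplace.partition_quantities(local, labels, partition.K)
    act = tuple(k for k in range(partition.K) if delta[k])
    out = _laplace.laplace_config_log_marginal(
        local, pq, act, hyper.mu0, hyper.tau2, hyper.delta0, hyper.sigma2)
    return float(out[0])


def config_log_prior(
    partition: Partition, delta: Sequence[int], p0: float, n_partitions: int
) -> float:
    """Uniform prior over partitions times iid Bernoulli block-null indicators.

    p0 is the probability that a block is *null* (Delta_k = 0); the limits
    p0 -> 0, 1 are handled as -inf where a configuration loses all mass.
    """
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must lie in [0, 1]")
    if n_partitions < 1:
        raise ValueError("n_partitions must be positive")
    delta = tuple(int(d) for d in delta)
    if len(delta) != partition.K:
        raise ValueError("delta must have one indicator per block")
    n_active = sum(delta)
    n_null = partition.K - n_active
    lp = -np.log(n_partitions)
    if n_null:
        lp += n_null * np.log(p0) if p0 > 0 else -np.inf
    if n_active:
        lp += n_active * np.log1p(-p0) if p0 < 1 else -np.inf
    return float(lp)


def _all_deltas(K: int):
    for n_active in range(K + 1):
        for act in combinations(range(K), n_active):
            delta = tuple(1 if k in act else 0 for k in range(K))
            yield delta, act


def posterior_over_configs(
    data: TwoGroupData, graph: Graph, hyper: Hyperparams, cap: int = 12
) -> ConfigPosterior:
    """Exhaustive discrete posterior over (partition, Delta) for a small graph."""
    if data.n_vertices != graph.n:
        raise ValueError("data rows must match graph order")
    if hyper.window_order != graph.n:
        raise ValueError("hyperparameter scale matrices must match graph order")
    partitions = enumerate_graph_respecting_partitions(graph, cap=cap)
    stats = sufficient_stats(data)
    local = _prepared_stats_batch(stats, hyper)
    configs: list[ModelConfig] = []
    logpost = []
    for part in partitions:
        pq = _laplace.partition_quantities(local, part.labels(), part.K)
        for delta, act in _all_deltas(part.K):
            lp = config_log_prior(part, delta, hyper.p0, len(partitions))
            if lp == -np.inf:
                configs.append(ModelConfig(part, delta, lp, np.nan))
                logpost.append(-np.inf)
                continue
            lm = float(_laplace.laplace_config_log_marginal(
                local, pq, act, hyper.mu0, hyper.tau2, hyper.delta0,
                hyper.sigma2)[0])
            configs.append(ModelConfig(part, delta, lp, lm))
            logpost.append(lp + lm)
    logpost = np.asarray(logpost)
    log_weights = logpost - logsumexp(logpost)
    return ConfigPosterior(graph=graph, configs=configs, log_weights=log_weights)


def local_fdr(post: ConfigPosterior, vertex: int) -> float:
    """Posterior probability that ``vertex`` sits in an unshifted block."""
    if not (0 <= vertex < post.graph.n):
        raise KeyError(f"vertex {vertex} not in graph")
    acc = -np.inf
    terms = []
    for cfg, lw in zip(post.configs, post.log_weights):
        if lw == -np.inf:
            continue
        k = cfg.partition.block_of(vertex)
        if cfg.delta[k] == 0:
            terms.append(lw)
    if not terms:
        return 0.0
    acc = logsumexp(np.asarray(terms))
    return float(min(1.0, np.exp(acc)))
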