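"""Empirical-Bayes hyperparameter estimation and preprocessing transforms.

Global hyperparameters are estimated once from data across the whole graph
and then shared by every local-subgraph computation.  All sub-estimators are
moment-based and individually swappable through :class:`EstimatorConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .graphs import Graph, window_offsets
from .model import Hyperparams, TwoGroupData

__all__ = [
    "EstimatorConfig",
    "EstimationReport",
    "normal_scores_transform",
    "low_variance_filter",
    "estimate_p0",
    "welch_pvalues",
    "estimate_hyperparams",
]


@dataclass
class EstimatorConfig:
    """Tunable knobs of the estimation recipe (floors, Storey lambda, shrinkage)."""

    tau2_floor: float = 1e-6
    sigma2_floor: float = 1e-6
    storey_lambda: float = 0.5
    diag_shrinkage: float = 0.5   # fraction of the window covariance pulled to its diagonal
    delta0: float = 0.0
    min_vertices: int = 50

    @classmethod
    def from_file(cls, path) -> "EstimatorConfig":
        """Read ``key = value`` overrides from a plain-text config file."""
        cfg = cls()
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                if not hasattr(cfg, key):
                    raise KeyError(f"unknown estimator option {key!r}")
                setattr(cfg, key, type(getattr(cfg, key))(val.strip()))
        return cfg


@dataclass
class EstimationReport:
    hyper: Hyperparams
    diagnostics: dict = field(default_factory=dict)


def normal_scores_transform(data: TwoGroupData) -> TwoGroupData:
    """Rank-based normal scores per vertex across the combined samples.

    Each vertex row is replaced by Phi^{-1}((rank - 0.5) / M) computed over
    the pooled M = M_X + M_Y samples (midranks for ties); the group split is
    unchanged.  Constant rows are flagged with a warning (their scores are 0).
    """
    combined = np.hstack([data.X, data.Y])
    M = combined.shape[1]
    const = np.ptp(combined, axis=1) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant vertex rows; normal scores set to 0",
            RuntimeWarning, stacklevel=2)
    ranks = sps.rankdata(combined, axis=1, method="average")
    scores = sps.norm.ppf((ranks - 0.5) / M)
    scores[const] = 0.0
    return TwoGroupData(scores[:, : data.M_X], scores[:, data.M_X:])


def low_variance_filter(data: TwoGroupData, quantile_threshold: float) -> np.ndarray:
    """Boolean keep-mask of vertices whose pooled marginal SD exceeds the
    given quantile of all SDs.  Threshold 0 keeps every vertex."""
    if not (0.0 <= quantile_threshold < 1.0):
        raise ValueError("quantile_threshold must lie in [0, 1)")
    sd = np.hstack([data.X, data.Y]).std(axis=1, ddof=1)
    if quantile_threshold == 0.0:
        return np.ones(data.n_vertices, dtype=bool)
    return sd > np.quantile(sd, quantile_threshold)


def estimate_p0(pvalues: np.ndarray, lam: float = 0.5) -> float:
    """Storey's null-proportion estimator at a fixed lambda (default 0.5),
    floored at 1/n and capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    est = np.mean(p > lam) / (1.0 - lam)
    return float(min(1.0, max(est, 1.0 / p.size)))


def welch_pvalues(data: TwoGroupData) -> np.ndarray:
    """Per-vertex two-sided Welch t-test p-values; degenerate rows get p = 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(data.X, data.Y, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} vertices with degenerate variance; p set to 1",
            RuntimeWarning, stacklevel=2)
        p[bad] = 1.0
    return p


def _mean_window_covariance(
    mat: np.ndarray, graph: Graph, kind: str
) -> tuple[np.ndarray | None, int]:
    """Average sample covariance of data restricted to full local windows."""
    offs = window_offsets(kind, len(graph.dims))
    n_w = len(offs)
    dims = graph.dims
    strides = np.array([1, dims[0], dims[0] * dims[1] if len(dims) == 3 else 0])
    coords = graph.coords
    rel = np.array([list(o) for o in offs])
    inside = np.ones(graph.n, dtype=bool)
    for a in range(len(dims)):
        lo, hi = -rel[:, a].min(), dims[a] - rel[:, a].max()
        inside &= (coords[:, a] >= lo) & (coords[:, a] < hi)
    centers = np.flatnonzero(inside)
    if centers.size == 0:
        return None, n_w
    shift = rel[:, : len(dims)] @ strides[: len(dims)]
    idx = centers[:, None] + shift[None, :]        # (V, n_w)
    W = mat[idx]                                   # (V, n_w, M)
    Wc = W - W.mean(axis=2, keepdims=True)
    covs = np.einsum("vnm,vkm->vnk", Wc, Wc) / (mat.shape[1] - 1)
    return covs.mean(axis=0), n_w


def estimate_hyperparams(
    data: TwoGroupData,
    graph: Graph,
    neighborhood: str = "star2d",
    config: EstimatorConfig | None = None,
) -> EstimationReport:
    """Moment-based empirical-Bayes estimates of all global hyperparameters.

    - mu0, tau2: mean and variance over vertices of the pooled per-vertex means
    - delta0 = 0 (symmetric two-sided testing); sigma2: variance over vertices
      of the group mean difference minus its average sampling variance
    - df = window order + 2; A, B = (df - n_w - 1) times the average full-window
      sample covariance of each group, shrunk toward its diagonal
    - p0: Storey estimate from per-vertex Welch t-test p-values
    """
    cfg = config or EstimatorConfig()
    diagnostics: dict = {"neighborhood": neighborhood}
    N = data.n_vertices
    if N != graph.n:
        raise ValueError("data rows must match graph order")
    small = N < cfg.min_vertices
    if small:
        warnings.warn(
            f"only {N} vertices; hyperparameter estimates widened to defaults",
            RuntimeWarning, stacklevel=2)

    pooled = np.hstack([data.X, data.Y]).mean(axis=1)
    mu0 = float(pooled.mean())
    tau2 = float(max(pooled.var(ddof=1) if N > 1 else 0.0, cfg.tau2_floor))

    xbar = data.X.mean(axis=1)
    ybar = data.Y.mean(axis=1)
    varx = data.X.var(axis=1, ddof=1)
    vary = data.Y.var(axis=1, ddof=1)
    samp_var = (varx / data.M_X + vary / data.M_Y).mean()
    diff_var = (ybar - xbar).var(ddof=1) if N > 1 else 0.0
    sigma2 = float(max(diff_var - samp_var, cfg.sigma2_floor))

    covA, n_w = _mean_window_covariance(data.X, graph, neighborhood)
    covB, _ = _mean_window_covariance(data.Y, graph, neighborhood)
    df = float(n_w + 2)
    scale = df - n_w - 1.0  # = 1: inverse-Wishart mean equals the shrunk covariance
    if covA is None or covB is None:
        warnings.warn("no full local windows; falling back to diagonal scale",
                      RuntimeWarning, stacklevel=2)
        vbar = float(np.mean(np.concatenate([varx, vary])))
        covA = covB = vbar * np.eye(n_w)
    mats = []
    for cov in (covA, covB):
        sh = (1.0 - cfg.diag_shrinkage) * cov + cfg.diag_shrinkage * np.diag(np.diag(cov))
        mats.append(scale * sh)
    A, B = mats

    pvals = welch_pvalues(data)
    p0 = estimate_p0(pvals, cfg.storey_lambda)

    if small:
        tau2 = max(tau2, 1.0)
        sigma2 = max(sigma2, 1.0)

    hyper = Hyperparams(mu0=mu0, tau2=tau2, delta0=cfg.delta0, sigma2=sigma2,
                        df=df, A=A, B=B, p0=p0)
    diagnostics.update(
        window_order=n_w, pooled_mean_var=diff_var, mean_sampling_var=float(samp_var),
        n_vertices=N, small_sample_fallback=small,
        methods={"mu0": "mean of pooled means", "tau2": "variance of pooled means",
                 "sigma2": "moment (diff variance minus sampling variance)",
                 "p0": f"storey(lambda={cfg.storey_lambda})",
                 "A,B": f"window covariance, {cfg.diag_shrinkage:.0%} diagonal shrinkage"},
    )
    return EstimationReport(hyper=hyper, diagnostics=diagnostics)
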