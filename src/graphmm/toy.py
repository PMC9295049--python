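"""Two-pair toy system: blocking raises power for a mean-difference test.

Each unit carries two variables per condition, (x1, x2) and (y1, y2), with
latent means drawn standard normal across the system and observation noise
of known variance sigma2.  A unit is *null* when the tested pair shares its
mean (mu_x1 = mu_y1) and *blocked* when the second variable duplicates the
first's means in both conditions (mu_x1 = mu_x2 and mu_y1 = mu_y2); the two
events are independent Bernoulli(p0) and Bernoulli(p_block).

``toy_lfdr1`` scores the null from (x1, y1) alone; ``toy_lfdr2`` mixes over
the blocking state as well, so concordant second-pair data sharpen the
test.  Component covariances are built as sigma2*I + Z Z' with Z the
unit-to-latent-mean incidence, never entered by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ToyParams",
    "toy_simulate",
    "toy_lfdr1",
    "toy_lfdr2",
    "fdr_curve",
    "misspecification_experiment",
]


@dataclass
class ToyParams:
    """Generative parameters of the toy system."""

    p0: float = 0.8
    p_block: float = 0.5
    sigma2: float = 0.5
    n_pairs: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p0 <= 1.0 and 0.0 <= self.p_block <= 1.0):
            raise ValueError("p0 and p_block must lie in [0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


#: unit-to-mean incidence matrices Z per (null, blocked) state, observation
#: order (x1, x2, y1, y2); covariance of a component is sigma2*I + Z Z'.
_DESIGNS = {
    # null & blocked: one shared mean for all four observations
    (True, True): np.ones((4, 1)),
    # null & unblocked: shared mean for (x1, y1); free means for x2 and y2
    (True, False): np.array([[1.0, 0, 0], [0, 1, 0], [1, 0, 0], [0, 0, 1]]),
    # non-null & blocked: one mean per condition
    (False, True): np.array([[1.0, 0], [1, 0], [0, 1], [0, 1]]),
    # non-null & unblocked: four free means
    (False, False): np.eye(4),
}


def _component_cov(null: bool, blocked: bool, sigma2: float) -> np.ndarray:
    Z = _DESIGNS[(null, blocked)]
    return sigma2 * np.eye(4) + Z @ Z.T


def toy_simulate(params: ToyParams) -> pd.DataFrame:
    """Draw units from the toy system; truth columns record the latent states."""
    rng = np.random.default_rng(params.seed)
    n = params.n_pairs
    is_null = rng.random(n) < params.p0
    is_blocked = rng.random(n) < params.p_block
    sd = np.sqrt(params.sigma2)
    obs = np.empty((n, 4))
    for null in (True, False):
        for blocked in (True, False):
            sel = np.flatnonzero((is_null == null) & (is_blocked == blocked))
            if sel.size == 0:
                continue
            Z = _DESIGNS[(null, blocked)]
            means = rng.standard_normal((sel.size, Z.shape[1]))
            obs[sel] = means @ Z.T + rng.standard_normal((sel.size, 4)) * sd
    return pd.DataFrame(
        {"x1": obs[:, 0], "x2": obs[:, 1], "y1": obs[:, 2], "y2": obs[:, 3],
         "is_null": is_null, "is_blocked": is_blocked})


def toy_lfdr1(x1, y1, params: ToyParams) -> np.ndarray:
    """P(null | x1, y1): two-component mixture over the null state only.

    The null predictive f is bivariate normal with margins N(0, 1 + sigma2)
    and correlation 1/(1 + sigma2); the non-null predictive factors as
    g(x1) g(y1) with g = N(0, 1 + sigma2).
    """
    x1 = np.asarray(x1, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    v = 1.0 + params.sigma2
    lg = sps.norm.logpdf(x1, scale=np.sqrt(v)) + sps.norm.logpdf(y1, scale=np.sqrt(v))
    cov = np.array([[v, 1.0], [1.0, v]])
    lf = sps.multivariate_normal.logpdf(np.stack([x1, y1], axis=-1), cov=cov)
    return _posterior_from_logs([lf, lg], [params.p0, 1.0 - params.p0], null_components=[0])


def toy_lfdr2(x1, x2, y1, y2, params: ToyParams) -> np.ndarray:
    """P(null | all four observations): mixture over null x blocking states."""
    pts = np.stack([np.asarray(x1, float), np.asarray(x2, float),
                    np.asarray(y1, float), np.asarray(y2, float)], axis=-1)
    logs, weights, null_idx = [], [], []
    i = 0
    for null in (True, False):
        for blocked in (True, False):
            w = (params.p0 if null else 1.0 - params.p0) * (
                params.p_block if blocked else 1.0 - params.p_block)
            logs.append(sps.multivariate_normal.logpdf(
                pts, cov=_component_cov(null, blocked, params.sigma2)))
            weights.append(w)
            if null:
                null_idx.append(i)
            i += 1
    return _posterior_from_logs(logs, weights, null_idx)


def _posterior_from_logs(logs, weights, null_components):
    logs = np.stack([np.asarray(l, dtype=float) for l in logs], axis=0)
    with np.errstate(divide="ignore"):
        lw = np.log(np.asarray(weights, dtype=float))[:, None]
    flat = logs.reshape(logs.shape[0], -1) + lw
    m = flat.max(axis=0)
    num = np.exp(flat[null_components] - m).sum(axis=0)
    den = np.exp(flat - m).sum(axis=0)
    out = num / den
    return out.reshape(logs.shape[1:]) if logs.ndim > 1 else float(out[0])


def fdr_curve(scores: np.ndarray, is_null: np.ndarray) -> pd.DataFrame:
    """FDR of the ranked list as a function of list size.

    Units are ranked by score ascending; at each prefix size the empirical
    FDR averages the truth indicators and the estimated FDR averages the
    scores themselves (the controlled rate).
    """
    scores = np.asarray(scores, dtype=float)
    is_null = np.asarray(is_null, dtype=bool)
    if scores.shape != is_null.shape:
        raise ValueError("scores and truth must be aligned")
    order = np.lexsort((np.arange(scores.size), scores))
    sizes = np.arange(1, scores.size + 1)
    emp = np.cumsum(is_null[order]) / sizes
    est = np.cumsum(scores[order]) / sizes
    return pd.DataFrame({"list_size": sizes, "fdr_empirical": emp, "fdr_estimated": est})


def misspecification_experiment(
    gen_p_block: float, assumed_p_block: float, params: ToyParams,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Generate with one blocking rate, score with another, tabulate FDR.

    For each lfdr threshold c the table reports the realized (empirical)
    FDR and the controlled FDR of the list {unit: lfdr2 <= c}.  Scoring
    with an understated blocking rate keeps the realized FDR below the
    nominal level; overstating it can lose control.
    """
    from dataclasses import replace

    gen = replace(params, p_block=gen_p_block)
    units = toy_simulate(gen)
    assumed = replace(params, p_block=assumed_p_block)
    scores = toy_lfdr2(units.x1, units.x2, units.y1, units.y2, assumed)
    if thresholds is None:
        thresholds = np.round(np.arange(0.05, 1.0, 0.05), 2)
    rows = []
    is_null = units.is_null.to_numpy()
    for c in thresholds:
        sel = scores <= c
        m = int(sel.sum())
        emp = float(is_null[sel].mean()) if m else np.nan
        ctrl = float(scores[sel].mean()) if m else np.nan
        rows.append((float(c), m, emp, ctrl))
    return pd.DataFrame(rows, columns=["threshold", "list_size",
                                       "fdr_empirical", "fdr_controlled"])
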