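"""Independent oracles used by the test suite.

Everything here evaluates the model's integrals by a route disjoint from
the package's Laplace/log1p machinery: direct determinant evaluation of the
marginal density on quadrature grids or under importance sampling, and
brute-force combinatorial enumeration via sympy.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy import stats as sps
from scipy.special import logsumexp, multigammaln


def brute_force_set_partitions(n: int):
    """All set partitions of range(n) via sympy (independent enumeration)."""
    from sympy.utilities.iterables import multiset_partitions

    for blocks in multiset_partitions(list(range(n))):
        yield tuple(tuple(sorted(b)) for b in blocks)


def block_connected(block, edges) -> bool:
    """Plain BFS connectivity of an induced block (no bitmask tricks)."""
    block = set(block)
    if not block:
        return False
    seen = {next(iter(block))}
    frontier = set(seen)
    while frontier:
        nxt = set()
        for u, v in edges:
            if u in frontier and v in block and v not in seen:
                nxt.add(v)
            if v in frontier and u in block and u not in seen:
                nxt.add(u)
        seen |= nxt
        frontier = nxt
    return seen == block


def log_matrix_t_direct(stats, muX, muY, hyper) -> np.ndarray:
    """Direct (slogdet-based) evaluation of the marginal data density for a
    batch of mean vectors; muX, muY have shape (G, n)."""
    n = stats.xbar.shape[0]
    MX, MY, df = stats.M_X, stats.M_Y, hyper.df
    A0 = hyper.A + (MX - 1) * stats.S1
    B0 = hyper.B + (MY - 1) * stats.T1
    dx = stats.xbar[None] - muX
    dy = stats.ybar[None] - muY
    At = A0[None] + MX * np.einsum("gi,gj->gij", dx, dx)
    Bt = B0[None] + MY * np.einsum("gi,gj->gij", dy, dy)
    logC = 0.0
    for M in (MX, MY):
        logC += (-0.5 * n * M * np.log(np.pi)
                 + multigammaln(0.5 * (df + M), n) - multigammaln(0.5 * df, n))
    return (logC
            + 0.5 * df * (np.linalg.slogdet(hyper.A)[1] + np.linalg.slogdet(hyper.B)[1])
            - 0.5 * (df + MX) * np.linalg.slogdet(At)[1]
            - 0.5 * (df + MY) * np.linalg.slogdet(Bt)[1])


def is_config_marginal(stats, part, delta, hyper, n_samples=200_000, seed=0,
                       scale_infl=1.6, tdf=5) -> float:
    """Importance-sampling estimate of one configuration's log marginal.

    Student-t proposal centered at moment-based block means; independent of
    the package's Newton/Laplace path.
    """
    rng = np.random.default_rng(seed)
    K = part.K
    act = [k for k in range(K) if delta[k]]
    a = len(act)
    d = K + a
    labels = part.labels()
    sizes = np.bincount(labels, minlength=K).astype(float)
    sx2 = max(np.diag(stats.S1).mean(), 1e-3)
    sy2 = max(np.diag(stats.T1).mean(), 1e-3)
    phi_c = np.bincount(labels, weights=stats.xbar, minlength=K) / sizes
    dlt_c = (np.bincount(labels, weights=stats.ybar - stats.xbar, minlength=K) / sizes)[act]
    prec_phi = 1.0 / hyper.tau2 + sizes * (stats.M_X / sx2 + stats.M_Y / sy2)
    prec_dlt = 1.0 / hyper.sigma2 + sizes[act] * stats.M_Y / sy2
    center = np.concatenate([phi_c, dlt_c])
    sd = scale_infl * np.concatenate([1 / np.sqrt(prec_phi), 1 / np.sqrt(prec_dlt)])
    z = rng.standard_t(tdf, size=(n_samples, d))
    pts = center + sd * z
    logq = (sps.t.logpdf(z, tdf) - np.log(sd)).sum(axis=1)
    phi = pts[:, :K]
    nu = phi.copy()
    if a:
        nu[:, act] = nu[:, act] + pts[:, K:]
    logf = log_matrix_t_direct(stats, phi[:, labels], nu[:, labels], hyper)
    logprior = sps.norm.logpdf(phi, hyper.mu0, np.sqrt(hyper.tau2)).sum(axis=1)
    if a:
        logprior += sps.norm.logpdf(pts[:, K:], hyper.delta0,
                                    np.sqrt(hyper.sigma2)).sum(axis=1)
    return float(logsumexp(logf + logprior - logq) - np.log(n_samples))


def invgamma_group_marginal(samples, mu, a, df) -> float:
    """N=1 oracle: integrate the Gaussian likelihood against the
    inverse-gamma prior on the variance by adaptive quadrature."""
    def f(v):
        return (np.prod(sps.norm.pdf(samples, mu, np.sqrt(v)))
                * sps.invgamma.pdf(v, df / 2, scale=a / 2))
    val, _ = integrate.quad(f, 0, np.inf, limit=300)
    return float(np.log(val))


def wishart_group_marginal(samples, mu, S, df, lim=8.0) -> float:
    """N=2 oracle: adaptive tplquad over the Cholesky factor of the
    precision matrix W = U^{-1} ~ Wishart(S^{-1}, df)."""
    D = samples - np.asarray(mu)[:, None]
    M = D.shape[1]
    logdetS = np.linalg.slogdet(S)[1]
    lognorm_w = -df * np.log(2.0) + 0.5 * df * logdetS - multigammaln(0.5 * df, 2)
    c0, c1, c2 = D[0] @ D[0], D[0] @ D[1], D[1] @ D[1]

    def integrand(l21, l11, l22):
        w11 = l11 * l11
        w12 = l11 * l21
        w22 = l21 * l21 + l22 * l22
        logdetW = 2 * np.log(l11) + 2 * np.log(l22)
        loglik = -M * np.log(2 * np.pi) + 0.5 * M * logdetW - 0.5 * (
            w11 * c0 + 2 * w12 * c1 + w22 * c2)
        logw = lognorm_w + 0.5 * (df - 3) * logdetW - 0.5 * (
            S[0, 0] * w11 + 2 * S[0, 1] * w12 + S[1, 1] * w22)
        logjac = np.log(4.0) + 2 * np.log(l11) + np.log(l22)
        return np.exp(loglik + logw + logjac)

    val, _ = integrate.tplquad(integrand, 1e-8, lim, 1e-8, lim, -lim, lim,
                               epsabs=1e-13, epsrel=1e-10)
    return float(np.log(val))


def toy_null_posterior_quadrature(x1, x2, y1, y2, p0, p_block, sigma2,
                                  nodes=80) -> float:
    """Integration oracle for the toy 4-variate mixture posterior.

    Each component's predictive density is obtained by Gauss-Hermite
    integration over its free latent means (1-4 dims), not from the
    closed-form covariances the implementation uses.
    """
    z, w = np.polynomial.hermite_e.hermegauss(nodes)
    logw1 = np.log(w) - 0.5 * np.log(2 * np.pi)
    sd = np.sqrt(sigma2)
    obs = np.array([x1, x2, y1, y2])

    def comp_logdens(design):
        # design: list of index-lists; observation i has mean m_{j} iff i in design[j]
        dsum = None
        for j, idxs in enumerate(design):
            contrib = sps.norm.logpdf(obs[idxs][:, None], z[None, :], sd).sum(axis=0)
            term = logsumexp(contrib + logw1)  # integral over mean j
            dsum = term if dsum is None else dsum + term
        return dsum

    designs = {
        (True, True): [[0, 1, 2, 3]],
        (True, False): [[0, 2], [1], [3]],
        (False, True): [[0, 1], [2, 3]],
        (False, False): [[0], [1], [2], [3]],
    }
    logs, weights, null_flags = [], [], []
    for (null, blocked), design in designs.items():
        wgt = (p0 if null else 1 - p0) * (p_block if blocked else 1 - p_block)
        logs.append(comp_logdens(design))
        weights.append(wgt)
        null_flags.append(null)
    logs = np.array(logs)
    with np.errstate(divide="ignore"):
        lw = logs + np.log(weights)
    num = logsumexp(lw[np.array(null_flags)])
    return float(np.exp(num - logsumexp(lw)))
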