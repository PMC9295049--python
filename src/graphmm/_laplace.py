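"""Batched Laplace marginalization of block means for the mixture model.

Everything here operates on a *batch* of local problems that share the same
subgraph shape (so the same partition list and design matrices) but have
different data.  The whole-lattice engine batches all same-shape vertices;
the single-graph API uses a batch of size one, so both paths run the exact
same arithmetic.

For a partition with K blocks and an active set of a shifted blocks, the
integrand over theta = (phi_1..phi_K, delta_(active)) is

    log f(X, Y | mu_X, mu_Y)  +  sum_k log N(phi_k | mu0, tau2)
                              +  sum_(active) log N(delta_k | delta0, sigma2)

with mu_X = P phi and mu_Y = P (phi + E delta), P the vertex-to-block
incidence.  By the matrix determinant lemma the data term reduces to

    const - aX*log1p(MX*qX) - aY*log1p(MY*qY),

where qX, qY are quadratic forms in theta, so gradients and Hessians are
available in closed form and a damped Newton ascent finds the mode in a
handful of iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import multigammaln

_LOG2PI = np.log(2.0 * np.pi)


def guarded_cholesky(
    mats: np.ndarray, label: str = "scale matrix"
) -> tuple[np.ndarray, np.ndarray]:
    """Batched Cholesky with a tiny trace-scaled ridge fallback.

    ``mats`` has shape (V, n, n).  Matrices failing the factorization get
    ``eps*I`` with ``eps = 1e-8 * trace/n`` added (repeatedly, growing by
    10x) and a warning is emitted; this mirrors a full-rank adjustment of
    the sample covariances.  Returns ``(chol, mats)`` where ``mats`` carries
    any ridge that was applied.
    """
    mats = np.ascontiguousarray(mats)
    try:
        return np.linalg.cholesky(mats), mats
    except np.linalg.LinAlgError:
        pass
    mats = mats.copy()
    out = np.empty_like(mats)
    n = mats.shape[-1]
    for i in range(mats.shape[0]):
        m = mats[i]
        eps = 1e-8 * np.trace(m) / n
        if not np.isfinite(eps) or eps <= 0:
            eps = 1e-8
        for _ in range(30):
            try:
                out[i] = np.linalg.cholesky(m)
                break
            except np.linalg.LinAlgError:
                warnings.warn(
                    f"{label} not positive definite; adding ridge {eps:.3e}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                m = m + eps * np.eye(n)
                eps *= 10.0
        else:
            raise np.linalg.LinAlgError(f"could not regularize {label} to PD")
        mats[i] = m
    return out, mats


def _chol_logdet(chol: np.ndarray) -> np.ndarray:
    d = np.diagonal(chol, axis1=-2, axis2=-1)
    return 2.0 * np.sum(np.log(d), axis=-1)


@dataclass
class LocalBatch:
    """Per-vertex sufficient quantities for a batch sharing one subgraph shape."""

    xbar: np.ndarray   # (V, n)
    ybar: np.ndarray   # (V, n)
    Ainv: np.ndarray   # (V, n, n) inverse of A + (MX-1) S1
    Binv: np.ndarray   # (V, n, n) inverse of B + (MY-1) T1
    const_f: np.ndarray  # (V,) config-independent part of the log density
    MX: int
    MY: int
    df: float

    @property
    def V(self) -> int:
        return self.xbar.shape[0]

    @property
    def n(self) -> int:
        return self.xbar.shape[1]


def log_density_constant(n: int, MX: int, MY: int, df: float) -> float:
    """Absolute normalizing constant C of the matrix-T marginal (log scale)."""
    out = 0.0
    for M in (MX, MY):
        out += -0.5 * n * M * np.log(np.pi)
        out += multigammaln(0.5 * (df + M), n) - multigammaln(0.5 * df, n)
    return out


def build_local_batch(
    X: np.ndarray, Y: np.ndarray, A: np.ndarray, B: np.ndarray, df: float
) -> LocalBatch:
    """Precompute batched inverses/determinants from raw local data.

    ``X`` has shape (V, n, MX) and ``Y`` (V, n, MY).
    """
    V, n, MX = X.shape
    MY = Y.shape[2]
    xbar = X.mean(axis=2)
    ybar = Y.mean(axis=2)
    Xc = X - xbar[:, :, None]
    Yc = Y - ybar[:, :, None]
    A0 = A[None] + np.einsum("vnm,vkm->vnk", Xc, Xc)
    B0 = B[None] + np.einsum("vnm,vkm->vnk", Yc, Yc)
    cholA, A0 = guarded_cholesky(A0, "A + (M_X-1) S1")
    cholB, B0 = guarded_cholesky(B0, "B + (M_Y-1) T1")
    logdetA0 = _chol_logdet(cholA)
    logdetB0 = _chol_logdet(cholB)
    Ainv = np.linalg.inv(A0)
    Binv = np.linalg.inv(B0)
    # symmetrize against roundoff
    Ainv = 0.5 * (Ainv + np.swapaxes(Ainv, 1, 2))
    Binv = 0.5 * (Binv + np.swapaxes(Binv, 1, 2))
    sA = np.linalg.slogdet(A)[1]
    sB = np.linalg.slogdet(B)[1]
    aX = 0.5 * (df + MX)
    aY = 0.5 * (df + MY)
    const = (
        log_density_constant(n, MX, MY, df)
        + 0.5 * df * (sA + sB)
        - aX * logdetA0
        - aY * logdetB0
    )
    return LocalBatch(xbar=xbar, ybar=ybar, Ainv=Ainv, Binv=Binv,
                      const_f=const, MX=MX, MY=MY, df=df)


@dataclass
class PartitionQuantities:
    """Quadratic-form pieces of one partition, batched over vertices."""

    P: np.ndarray       # (n, K) incidence
    sizes: np.ndarray   # (K,)
    GX: np.ndarray      # (V, K, K)  P' Ainv P
    gX: np.ndarray      # (V, K)     P' Ainv xbar
    cX: np.ndarray      # (V,)       xbar' Ainv xbar
    GB: np.ndarray      # (V, K, K)
    gB: np.ndarray      # (V, K)
    cY: np.ndarray      # (V,)
    phi0: np.ndarray    # (V, K) data-driven start for phi
    d0: np.ndarray      # (V, K) data-driven start for delta (per block)


def partition_quantities(local: LocalBatch, labels: np.ndarray, K: int) -> PartitionQuantities:
    P = np.zeros((local.n, K))
    P[np.arange(local.n), labels] = 1.0
    sizes = P.sum(axis=0)
    ax = np.einsum("vnk,vk->vn", local.Ainv, local.xbar)
    by = np.einsum("vnk,vk->vn", local.Binv, local.ybar)
    GX = np.einsum("ni,vnk,kj->vij", P, local.Ainv, P)
    GB = np.einsum("ni,vnk,kj->vij", P, local.Binv, P)
    gX = np.einsum("ni,vn->vi", P, ax)
    gB = np.einsum("ni,vn->vi", P, by)
    cX = np.einsum("vn,vn->v", local.xbar, ax)
    cY = np.einsum("vn,vn->v", local.ybar, by)
    phi0 = (local.xbar @ P) / sizes
    d0 = ((local.ybar - local.xbar) @ P) / sizes
    return PartitionQuantities(P=P, sizes=sizes, GX=GX, gX=gX, cX=cX,
                               GB=GB, gB=gB, cY=cY, phi0=phi0, d0=d0)


def _objective(pq, act, theta, K, aX, aY, MX, MY, mu0, tau2, delta0, sigma2):
    phi = theta[:, :K]
    nu = phi.copy()
    if len(act):
        nu[:, act] += theta[:, K:]
    qX = pq.cX - 2.0 * np.einsum("vk,vk->v", phi, pq.gX) + np.einsum(
        "vi,vij,vj->v", phi, pq.GX, phi)
    qY = pq.cY - 2.0 * np.einsum("vk,vk->v", nu, pq.gB) + np.einsum(
        "vi,vij,vj->v", nu, pq.GB, nu)
    qX = np.maximum(qX, 0.0)
    qY = np.maximum(qY, 0.0)
    h = (
        -aX * np.log1p(MX * qX)
        - aY * np.log1p(MY * qY)
        - 0.5 * np.sum((phi - mu0) ** 2, axis=1) / tau2
    )
    if len(act):
        h -= 0.5 * np.sum((theta[:, K:] - delta0) ** 2, axis=1) / sigma2
    return h, phi, nu, qX, qY


def _grad_hess(pq, act, theta, K, aX, aY, MX, MY, mu0, tau2, delta0, sigma2):
    h, phi, nu, qX, qY = _objective(pq, act, theta, K, aX, aY, MX, MY,
                                    mu0, tau2, delta0, sigma2)
    a = len(act)
    d = K + a
    V = theta.shape[0]
    rX = 2.0 * (np.einsum("vij,vj->vi", pq.GX, phi) - pq.gX)
    rY = 2.0 * (np.einsum("vij,vj->vi", pq.GB, nu) - pq.gB)
    bX = aX * MX / (1.0 + MX * qX)
    bY = aY * MY / (1.0 + MY * qY)
    cXq = aX * MX**2 / (1.0 + MX * qX) ** 2
    cYq = aY * MY**2 / (1.0 + MY * qY) ** 2

    grad = np.zeros((V, d))
    grad[:, :K] = -bX[:, None] * rX - bY[:, None] * rY - (phi - mu0) / tau2
    if a:
        grad[:, K:] = -bY[:, None] * rY[:, act] - (theta[:, K:] - delta0) / sigma2

    HX = -2.0 * bX[:, None, None] * pq.GX + cXq[:, None, None] * np.einsum(
        "vi,vj->vij", rX, rX)
    Hnu = -2.0 * bY[:, None, None] * pq.GB + cYq[:, None, None] * np.einsum(
        "vi,vj->vij", rY, rY)
    H = np.zeros((V, d, d))
    H[:, :K, :K] = HX + Hnu
    H[:, range(K), range(K)] -= 1.0 / tau2
    if a:
        H[:, :K, K:] = Hnu[:, :, act]
        H[:, K:, :K] = Hnu[:, act, :]
        H[:, K:, K:] = Hnu[:, act, :][:, :, act]
        H[:, range(K, d), range(K, d)] -= 1.0 / sigma2
    return h, grad, H


def laplace_config_log_marginal(
    local: LocalBatch,
    pq: PartitionQuantities,
    act: tuple[int, ...],
    mu0: float,
    tau2: float,
    delta0: float,
    sigma2: float,
    max_iter: int = 80,
    gtol: float = 1e-8,
) -> np.ndarray:
    """Laplace-approximated log marginal density for one (partition, Delta).

    Returns shape (V,): log of the integral of the joint density of data and
    free means over theta, per batch element.
    """
    K = pq.sizes.shape[0]
    act = tuple(act)
    a = len(act)
    d = K + a
    V = local.V
    aX = 0.5 * (local.df + local.MX)
    aY = 0.5 * (local.df + local.MY)
    args = (K, aX, aY, local.MX, local.MY, mu0, tau2, delta0, sigma2)

    theta = np.concatenate([pq.phi0, pq.d0[:, act]], axis=1) if a else pq.phi0.copy()
    h, grad, H = _grad_hess(pq, act, theta, *args)
    lam = np.zeros(V)
    eye = np.eye(d)
    slack = 1e-9  # tolerate float noise in h near the mode (|h| is O(100))
    for _ in range(max_iter):
        scale = 1.0 + np.max(np.abs(theta), axis=1)
        active = np.max(np.abs(grad), axis=1) > gtol * (1.0 + np.abs(h)) / scale
        if not active.any():
            break
        M = -H + lam[:, None, None] * eye
        try:
            step = np.linalg.solve(M, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            lam = lam * 10.0 + 1e-6
            continue
        # vanishing steps mean we are at the mode regardless of the grad test
        active &= np.max(np.abs(step), axis=1) > 1e-12 * scale
        if not active.any():
            break
        t = np.ones(V)
        improved = ~active  # inactive elements are already fine
        for _ in range(30):
            cand = theta + (t * active)[:, None] * step
            h_new = _objective(pq, act, cand, *args)[0]
            better = h_new >= h - slack
            newly = active & better & ~improved
            theta[newly] = cand[newly]
            h = np.where(newly, h_new, h)
            improved |= newly
            if improved.all():
                break
            t = np.where(improved, t, t / 2.0)
        stuck = active & ~improved
        lam = np.where(stuck, lam * 10.0 + 1e-6, lam / 2.0)
        h, grad, H = _grad_hess(pq, act, theta, *args)

    negH = -H
    sign, logdet = np.linalg.slogdet(negH)
    bad = sign <= 0
    if bad.any():
        # ridge the rare indefinite mode just enough to evaluate the volume
        for i in np.flatnonzero(bad):
            w = np.linalg.eigvalsh(negH[i])
            ridge = max(1e-10, 1e-8 - w.min()) if w.min() < 1e-8 else 1e-10
            logdet[i] = np.linalg.slogdet(negH[i] + ridge * np.eye(d))[1]

    prior_const = -0.5 * K * np.log(2.0 * np.pi * tau2)
    if a:
        prior_const -= 0.5 * a * np.log(2.0 * np.pi * sigma2)
    return local.const_f + prior_const + h + 0.5 * d * _LOG2PI - 0.5 * logdet
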