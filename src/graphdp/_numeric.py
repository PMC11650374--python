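"""Shared numerical kernels: simplex-safe Dirichlet sampling and log densities.

Dirichlet draws with very small shapes (e.g. alpha/L at large L) underflow to
exact zeros when sampled as normalized gammas in linear space.  We therefore
sample every gamma variate in log space through the shape-boost identity
Gamma(a) =d Gamma(a+1) * U^(1/a), normalize with log-sum-exp, and floor the
result, so simplex states stay strictly positive.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import gammaln, logsumexp

SIMPLEX_FLOOR = 1e-300


def sample_dirichlet(rng: np.random.Generator, alpha, size: int | None = None):
    """Draw from Dirichlet(alpha), robust to tiny shape parameters.

    Parameters
    ----------
    rng : numpy Generator
    alpha : array-like, shape (L,)
        Strictly positive concentration vector.
    size : int, optional
        If given, return ``size`` i.i.d. draws, shape (size, L).
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet shapes must be strictly positive")
    shape = (alpha.size,) if size is None else (size, alpha.size)
    # log Gamma(a) via the boost identity, valid for every a > 0
    log_g = np.log(rng.gamma(alpha + 1.0, size=shape))
    log_u = np.log1p(-rng.uniform(size=shape))  # log of U(0,1], never -inf
    with np.errstate(over="ignore"):  # subnormal shapes push log_u/alpha to -inf
        log_g = log_g + log_u / alpha
    log_g -= logsumexp(log_g, axis=-1, keepdims=True)
    x = np.exp(log_g)
    x = np.maximum(x, SIMPLEX_FLOOR)
    x /= x.sum(axis=-1, keepdims=True)
    return x


def sample_dirichlet_rows(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """One Dirichlet draw per row of a matrix of concentration vectors."""
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet shapes must be strictly positive")
    with np.errstate(over="ignore"):
        log_g = np.log(rng.gamma(alpha + 1.0)) + np.log1p(-rng.uniform(size=alpha.shape)) / alpha
    log_g -= logsumexp(log_g, axis=-1, keepdims=True)
    x = np.maximum(np.exp(log_g), SIMPLEX_FLOOR)
    return x / x.sum(axis=-1, keepdims=True)


def dirichlet_logpdf(x, alpha) -> float:
    """Log density of Dirichlet(alpha) at x (floored away from the boundary)."""
    x = np.maximum(np.asarray(x, dtype=float), SIMPLEX_FLOOR)
    alpha = np.asarray(alpha, dtype=float)
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * np.log(x)).sum()
    )


def gamma_logpdf(x: float, shape: float, rate: float = 1.0) -> float:
    """Log density of Gamma(shape, rate) at x."""
    if x <= 0:
        return -np.inf
    return float(shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x)


def mvn_logpdf_atoms(x: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Gaussian log densities of n points under L (mean, covariance) atoms.

    Parameters
    ----------
    x : (n, d) array
    means : (L, d) array
    covs : (L, d, d) array

    Returns
    -------
    (n, L) array of log densities.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, d = x.shape
    chols = np.linalg.cholesky(covs)  # (L, d, d), batched
    logdets = 2.0 * np.log(np.diagonal(chols, axis1=1, axis2=2)).sum(axis=1)
    dev = x[None, :, :] - means[:, None, :]  # (L, n, d)
    sol = np.linalg.solve(chols, dev.transpose(0, 2, 1))  # (L, d, n)
    maha = np.einsum("ldn,ldn->ln", sol, sol)
    return (-0.5 * (d * np.log(2.0 * np.pi) + logdets[:, None] + maha)).T


def sample_invwishart(
    rng: np.random.Generator, df: float, psi: np.ndarray, size: int = 1
) -> np.ndarray:
    """Inverse-Wishart draws via the Bartlett decomposition.

    Sigma ~ IW(df, psi) is the inverse of W ~ Wishart(df, psi^{-1}).
    """
    psi = np.asarray(psi, dtype=float)
    d = psi.shape[0]
    if df <= d - 1:
        raise ValueError("inverse-Wishart needs df > d - 1")
    # chol of psi^{-1} through chol of psi: psi = R R^T  =>  psi^{-1} = R^{-T} R^{-1}
    R = np.linalg.cholesky(psi)
    out = np.empty((size, d, d))
    eye = np.eye(d)
    for s in range(size):
        A = np.zeros((d, d))
        for i in range(d):
            A[i, i] = np.sqrt(rng.chisquare(df - i))
            for j in range(i):
                A[i, j] = rng.standard_normal()
        # W = C A A^T C^T with C = chol(psi^{-1}) = R^{-T}; so
        # Sigma = W^{-1} = R A^{-T} A^{-1} R^T
        Ainv = solve_triangular(A, eye, lower=True)
        M = R @ Ainv.T
        out[s] = M @ M.T
    return out
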