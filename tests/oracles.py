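"""Independent reference implementations used only as test oracles.

Everything here is deliberately coded from first principles, separate from
the package internals: a pair-counting adjusted Rand index, a brute-force
posterior similarity matrix, direct Dirichlet/NIW density evaluations, and a
stand-alone truncated hierarchical DP (exchangeable-groups) blocked Gibbs
sampler for the fork-topology equivalence checks.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import multivariate_normal


def pair_count_ari(a, b) -> float:
    """Adjusted Rand index by direct pair counting over all item pairs."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    n = a.size
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    n11 = int(np.sum(same_a[iu] & same_b[iu]))
    n10 = int(np.sum(same_a[iu] & ~same_b[iu]))
    n01 = int(np.sum(~same_a[iu] & same_b[iu]))
    n00 = int(np.sum(~same_a[iu] & ~same_b[iu]))
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


def brute_psm(z_draws: np.ndarray) -> np.ndarray:
    """Posterior similarity by explicit O(N^2 * draws) pair counting."""
    n_draws, N = z_draws.shape
    psm = np.zeros((N, N))
    for d in range(n_draws):
        for a in range(N):
            for b in range(N):
                psm[a, b] += z_draws[d, a] == z_draws[d, b]
    return psm / n_draws


def dirichlet_logpdf_ref(x, alpha) -> float:
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    return float(
        gammaln(alpha.sum())
        - gammaln(alpha).sum()
        + ((alpha - 1.0) * np.log(np.maximum(x, 1e-300))).sum()
    )


# ---------------------------------------------------------------------------
# Stand-alone truncated HDP blocked Gibbs sampler (fork-topology oracle)
# ---------------------------------------------------------------------------


def _niw_posterior_ref(x, mean0, kappa0, psi, df):
    n = x.shape[0]
    if n == 0:
        return mean0, kappa0, psi, df
    xbar = x.mean(axis=0)
    dev = x - xbar
    S = dev.T @ dev
    kn = kappa0 + n
    mn = (kappa0 * mean0 + n * xbar) / kn
    diff = xbar - mean0
    return mn, kn, psi + S + kappa0 * n / kn * np.outer(diff, diff), df + n


def _draw_niw_ref(rng, mean0, kappa0, psi, df):
    from scipy.stats import invwishart

    cov = invwishart.rvs(df=df, scale=psi, random_state=rng)
    cov = np.atleast_2d(cov)
    mean = rng.multivariate_normal(mean0, cov / kappa0)
    return mean, cov


def run_hdp_gibbs_ref(
    x_by_group: dict,
    mean0,
    kappa0,
    psi,
    df,
    alpha0: float,
    L: int,
    n_iter: int,
    burn_in: int,
    thin: int,
    seed: int,
):
    """Truncated HDP mixture blocked Gibbs with the same hyperprior structure.

    Model: alpha_root ~ Gamma(alpha0, 1); global weights beta ~ Dir(alpha_root
    / L); per group j, alpha_j ~ Gamma(alpha_root, 1) and pi_j ~ Dir(alpha_j *
    beta); z_ji ~ pi_j; atoms from NIW(mean0, kappa0, psi, df); Gaussian
    observations.  beta is updated by an independence Metropolis step with a
    Dirichlet proposal centered on the current value; concentrations by
    log-scale random walks.  Returns pooled z draws (n_draws, N), groups in
    sorted key order, plus alpha_root draws.
    """
    rng = np.random.default_rng(seed)
    groups = sorted(x_by_group)
    mean0 = np.asarray(mean0, dtype=float)
    psi = np.asarray(psi, dtype=float)
    d = mean0.size
    X = np.vstack([x_by_group[j] for j in groups])
    sizes = [x_by_group[j].shape[0] for j in groups]
    offsets = np.cumsum([0] + sizes)
    N = X.shape[0]

    alpha_root = float(rng.gamma(alpha0))
    alpha_j = {j: float(rng.gamma(alpha_root)) for j in groups}
    beta = rng.dirichlet(np.full(L, max(alpha_root / L, 1e-3)))
    beta = np.maximum(beta, 1e-12)
    beta /= beta.sum()
    pi = {j: rng.dirichlet(np.maximum(alpha_j[j] * beta, 1e-6)) for j in groups}
    atoms = [_draw_niw_ref(rng, mean0, kappa0, psi, df) for _ in range(L)]
    z = rng.integers(0, L, size=N)

    kappa_prop = 300.0  # Dirichlet independence-proposal concentration
    z_draws, alpha_root_draws = [], []
    for it in range(n_iter):
        # atoms
        dens = np.empty((N, L))
        for l in range(L):
            xl = X[z == l]
            post = _niw_posterior_ref(xl, mean0, kappa0, psi, df)
            atoms[l] = _draw_niw_ref(rng, *post)
            # df = d prior draws can be numerically near-singular; regularize
            # relative to the matrix scale (scipy's PSD cutoff is relative)
            cov_l = atoms[l][1]
            cov_l = cov_l + (1e-8 * np.trace(cov_l) + 1e-12) * np.eye(d)
            dens[:, l] = multivariate_normal.logpdf(X, atoms[l][0], cov_l)
        # assignments via explicit inverse-cdf sampling
        for gi, j in enumerate(groups):
            sl = slice(offsets[gi], offsets[gi + 1])
            logp = np.log(np.maximum(pi[j], 1e-300))[None, :] + dens[sl]
            logp -= logp.max(axis=1, keepdims=True)
            p = np.exp(logp)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.uniform(size=p.shape[0])
            z[sl] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        # group weights (conjugate)
        for gi, j in enumerate(groups):
            counts = np.bincount(z[offsets[gi] : offsets[gi + 1]], minlength=L)
            pi[j] = rng.dirichlet(alpha_j[j] * beta + counts)
            pi[j] = np.maximum(pi[j], 1e-12)
            pi[j] /= pi[j].sum()
        # global weights: independence MH, Dirichlet proposal around current
        prop = rng.dirichlet(kappa_prop * beta)
        prop = np.maximum(prop, 1e-12)
        prop /= prop.sum()

        def beta_target(b):
            lp = dirichlet_logpdf_ref(b, np.full(L, alpha_root / L))
            for j in groups:
                lp += dirichlet_logpdf_ref(pi[j], alpha_j[j] * b)
            return lp

        log_acc = (
            beta_target(prop)
            - beta_target(beta)
            + dirichlet_logpdf_ref(beta, kappa_prop * prop)
            - dirichlet_logpdf_ref(prop, kappa_prop * beta)
        )
        if np.log(rng.uniform()) < log_acc:
            beta = prop
        # concentrations: log random walks
        cand = float(np.exp(np.log(alpha_root) + 0.2 * rng.normal()))

        def root_target(a):
            lp = (alpha0 - 1) * np.log(a) - a  # Gamma(alpha0, 1) kernel
            lp += dirichlet_logpdf_ref(beta, np.full(L, a / L))
            for j in groups:
                lp += (a - 1) * np.log(alpha_j[j]) - gammaln(a) - alpha_j[j]
            return lp

        if np.log(rng.uniform()) < root_target(cand) - root_target(alpha_root) + np.log(
            cand / alpha_root
        ):
            alpha_root = cand
        for j in groups:
            cand_j = float(np.exp(np.log(alpha_j[j]) + 0.2 * rng.normal()))

            def aj_target(a):
                lp = (alpha_root - 1) * np.log(a) - a - gammaln(alpha_root)
                lp += dirichlet_logpdf_ref(pi[j], a * beta)
                return lp

            if np.log(rng.uniform()) < aj_target(cand_j) - aj_target(
                alpha_j[j]
            ) + np.log(cand_j / alpha_j[j]):
                alpha_j[j] = cand_j
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            z_draws.append(z.copy())
            alpha_root_draws.append(alpha_root)
    return np.array(z_draws), np.array(alpha_root_draws)


def hdp_prior_weight_draws_ref(alpha_root, alpha_children, L, n_draws, seed):
    """Direct truncated-HDP prior draws of (beta, {beta_j}) at fixed alphas."""
    rng = np.random.default_rng(seed)
    beta = rng.dirichlet(np.full(L, alpha_root / L), size=n_draws)
    beta = np.maximum(beta, 1e-12)
    beta /= beta.sum(axis=1, keepdims=True)
    out = {}
    for j, a_j in alpha_children.items():
        g = rng.gamma(np.maximum(a_j * beta, 1e-12))
        bad = g.sum(axis=1) <= 0
        if bad.any():
            g[bad] = rng.gamma(np.maximum(a_j * beta[bad], 1e-3))
        out[j] = g / g.sum(axis=1, keepdims=True)
    return beta, out
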