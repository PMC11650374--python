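"""Metropolis-within-blocked-Gibbs sampler for the truncated GDP mixture.

The sampler works on the finite (truncation level L) representation of the
model.  Component indicators, mixture atoms, and each node's own mixing
weights have conjugate full conditionals (categorical, normal-inverse-
Wishart, Dirichlet) and are updated by exact Gibbs draws.  The root weights
beta^(0) and the hidden simplices nu_j^(k,m) appear as the *parameter* of
downstream Dirichlet factors and are therefore not conjugate; they are
updated coordinate-by-coordinate with a logit-simplex (SALT-style)
Metropolis proposal.  Concentration parameters get log-scale Gaussian
random-walk Metropolis steps targeting their gamma-DAG conditionals.
Proposal scales adapt toward a 0.44 acceptance rate during burn-in and are
frozen afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from ._numeric import dirichlet_logpdf, gamma_logpdf, mvn_logpdf_atoms, sample_dirichlet
from .dag_core import GroupDAG, ancestors
from .gdp_prior import (
    AssignmentState,
    AtomSet,
    ConcentrationState,
    GroupedDataset,
    NIWParams,
    WeightState,
    hidden_chain_concentrations,
    sample_atoms,
    sample_concentrations,
    sample_weight_state,
)

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "run_gibbs",
    "update_assignments",
    "update_atoms",
    "update_node_weights",
    "salt_propose",
    "update_hidden_weights",
    "update_concentrations",
    "loglik_trace",
]

_TARGET_ACCEPT = 0.44
_ADAPT_BATCH = 50


@dataclass
class SamplerConfig:
    n_iter: int = 3000
    burn_in: int = 1000
    thin: int = 5
    n_chains: int = 1
    seed: int = 0
    salt_scale: float = 1.0
    alpha_rw_scale: float = 0.2
    adapt: bool = True
    init_mode: str = "kmeans"  # or "prior"

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.init_mode not in ("kmeans", "prior"):
            raise ValueError("init_mode must be 'kmeans' or 'prior'")


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws, pooled across chains."""

    z: np.ndarray  # (n_draws, N) pooled component indicators
    group_of: np.ndarray  # (N,) group label of each pooled observation
    beta_root: np.ndarray  # (n_draws, L)
    beta: dict  # node -> (n_draws, L)
    nu: dict  # (node, m) -> (n_draws, L)
    alpha_root: np.ndarray  # (n_draws,)
    alpha: dict  # node -> (n_draws,)
    means: np.ndarray  # (n_draws, L, d)
    covs: np.ndarray  # (n_draws, L, d, d)
    loglik: np.ndarray  # (n_draws,)
    chain_id: np.ndarray  # (n_draws,)
    accept_rates: dict
    L: int = 0
    config: SamplerConfig | None = None

    @property
    def n_draws(self) -> int:
        return self.beta_root.shape[0]


def loglik_trace(samples: PosteriorSamples) -> np.ndarray:
    """Observation log-likelihood (categorical + Gaussian terms) per retained draw."""
    if samples.n_draws == 0:
        raise ValueError("no retained draws")
    return samples.loglik


# ---------------------------------------------------------------------------
# Conjugate blocks
# ---------------------------------------------------------------------------


def update_assignments(
    data: GroupedDataset,
    weights: WeightState,
    atoms: AtomSet,
    rng: np.random.Generator,
    dag: GroupDAG,
) -> AssignmentState:
    """Gibbs draw of all component indicators from their categorical conditionals."""
    X, _ = data.pooled()
    logf = mvn_logpdf_atoms(X, atoms.means, atoms.covs) if X.shape[0] else None
    z: dict = {}
    offset = 0
    for j in sorted(data.x):
        n_j = data.x[j].shape[0]
        if n_j == 0:
            z[j] = np.empty(0, dtype=np.int64)
            continue
        beta_j = weights.node_weights(dag, j)
        logp = (
            np.log(np.maximum(beta_j, 1e-300))[None, :]
            + logf[offset : offset + n_j]
        )
        offset += n_j
        if not np.all(np.isfinite(logp.max(axis=1))):
            raise FloatingPointError("all-zero unnormalized assignment weights")
        gumb = rng.gumbel(size=logp.shape)
        z[j] = np.argmax(logp + gumb, axis=1).astype(np.int64)
    return AssignmentState(z=z)


def _niw_posterior(x: np.ndarray, g0: NIWParams):
    """NIW posterior parameters given observations assigned to one component."""
    n = x.shape[0]
    if n == 0:
        return g0
    xbar = x.mean(axis=0)
    dev = x - xbar
    S = dev.T @ dev
    kappa_n = g0.kappa0 + n
    mean_n = (g0.kappa0 * g0.mean0 + n * xbar) / kappa_n
    diff = xbar - g0.mean0
    psi_n = g0.psi + S + (g0.kappa0 * n / kappa_n) * np.outer(diff, diff)
    return NIWParams(mean0=mean_n, kappa0=kappa_n, psi=psi_n, df=g0.df + n)


def update_atoms(
    data: GroupedDataset,
    z: AssignmentState,
    g0: NIWParams,
    L: int,
    rng: np.random.Generator,
) -> AtomSet:
    """Conjugate NIW draw of every atom; empty components draw from the prior."""
    d = g0.d
    X, _ = data.pooled()
    if X.shape[0]:
        zz = np.concatenate([np.asarray(z.z[j]) for j in sorted(data.x)])
    else:
        zz = np.empty(0, dtype=int)
    means = np.empty((L, d))
    covs = np.empty((L, d, d))
    for l in range(L):
        post = _niw_posterior(X[zz == l], g0)
        single = sample_atoms(post, 1, rng)
        means[l] = single.means[0]
        covs[l] = single.covs[0]
    return AtomSet(means=means, covs=covs)


def update_node_weights(
    counts: np.ndarray,
    nu_top: np.ndarray,
    alpha_node: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate Dirichlet draw of a node's mixing weights given its counts."""
    counts = np.asarray(counts, dtype=float)
    return sample_dirichlet(rng, alpha_node * np.asarray(nu_top) + counts)


# ---------------------------------------------------------------------------
# Logit-simplex (SALT) Metropolis
# ---------------------------------------------------------------------------


def salt_propose(
    current: np.ndarray, coord: int, scale: float, rng: np.random.Generator
):
    """Single-coordinate logit-scale proposal that stays on the simplex.

    The chosen coordinate moves by a Gaussian step on the logit scale; the
    remaining coordinates are rescaled proportionally so the vector still
    sums to one.  Returns the proposal and the log Hastings correction
    log|det J| = log[x'_c(1-x'_c)] - log[x_c(1-x_c)]
                 + (L-2) log[(1-x'_c)/(1-x_c)],
    the Jacobian of the reversible map on the (L-1)-dimensional simplex.
    """
    x = np.asarray(current, dtype=float)
    Ldim = x.size
    xc = x[coord]
    if not (0.0 < xc < 1.0):
        raise ValueError("current simplex coordinate must lie strictly in (0, 1)")
    y = logit(xc) + scale * rng.normal()
    xpc = float(np.clip(expit(y), 1e-13, 1.0 - 1e-13))
    s = (1.0 - xpc) / (1.0 - xc)
    proposal = x * s
    proposal[coord] = xpc
    proposal /= proposal.sum()  # cancel roundoff so repeated moves cannot drift
    log_h = (
        np.log(xpc)
        + np.log1p(-xpc)
        - np.log(xc)
        - np.log1p(-xc)
        + (Ldim - 2) * (np.log1p(-xpc) - np.log1p(-xc))
    )
    return proposal, float(log_h)


def salt_metropolis_sweep(
    x: np.ndarray,
    log_target,
    scale: float,
    rng: np.random.Generator,
    current_lp: float | None = None,
):
    """One full per-coordinate SALT Metropolis scan of a simplex.

    Returns (new_x, new_lp, n_accepted).
    """
    lp = log_target(x) if current_lp is None else current_lp
    accepted = 0
    for c in range(x.size):
        prop, log_h = salt_propose(x, c, scale, rng)
        lp_prop = log_target(prop)
        if np.log(rng.uniform()) < lp_prop - lp + log_h:
            x, lp = prop, lp_prop
            accepted += 1
    return x, lp, accepted


# ---------------------------------------------------------------------------
# Dirichlet factor registry: which chain factors involve which state pieces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Factor:
    """One Dirichlet factor of the weight chain: target ~ Dir(conc_sum * base).

    ``conc_nodes`` lists the nodes whose concentrations sum to the factor's
    total; ``base`` / ``target`` are state keys: "root", ("nu", j, m), or
    ("beta", j).
    """

    target: object
    base: object
    conc_nodes: tuple


def build_factors(dag: GroupDAG) -> list:
    factors = []
    for j in dag.node_ids:
        if j == dag.root:
            continue
        k = dag.layer[j]
        prev = "root"
        for m in range(2, k + 1):
            anc = tuple(sorted(ancestors(dag, j, k - m + 1)))
            factors.append(_Factor(target=("nu", j, m), base=prev, conc_nodes=anc))
            prev = ("nu", j, m)
        factors.append(_Factor(target=("beta", j), base=prev, conc_nodes=(j,)))
    return factors


def _get(weights: WeightState, key):
    if key == "root":
        return weights.beta_root
    kind = key[0]
    return weights.nu[(key[1], key[2])] if kind == "nu" else weights.beta[key[1]]


def _set(weights: WeightState, key, value):
    if key == "root":
        weights.beta_root = value
    elif key[0] == "nu":
        weights.nu[(key[1], key[2])] = value
    else:
        weights.beta[key[1]] = value


def _factor_logpdf(f: _Factor, weights: WeightState, conc: ConcentrationState, dag: GroupDAG):
    total = sum(conc.of(dag, a) for a in f.conc_nodes)
    return dirichlet_logpdf(_get(weights, f.target), total * _get(weights, f.base))


# ---------------------------------------------------------------------------
# Metropolis blocks
# ---------------------------------------------------------------------------


def update_hidden_weights(
    dag: GroupDAG,
    weights: WeightState,
    conc: ConcentrationState,
    rng: np.random.Generator,
    scales: dict,
    root_counts: np.ndarray | None = None,
    factors: list | None = None,
    accept: dict | None = None,
) -> WeightState:
    """SALT Metropolis update of beta^(0) and every hidden simplex nu_j^(k,m).

    Each simplex targets its full conditional: its own Dirichlet prior factor
    times every Dirichlet factor in which it is the base, plus (for an
    observed root) the multinomial term of the root group's assignments.
    Updates happen in place; acceptance counts accumulate in ``accept``.
    """
    if factors is None:
        factors = build_factors(dag)
    L = weights.L

    def sweep(key, prior_terms, dependents):
        def log_target(x):
            old = _get(weights, key)
            _set(weights, key, x)
            try:
                lp = prior_terms(x)
                for f in dependents:
                    lp += _factor_logpdf(f, weights, conc, dag)
            finally:
                _set(weights, key, old)
            return lp

        x = _get(weights, key)
        scale = scales.get(key, 1.0)
        new_x, _, n_acc = salt_metropolis_sweep(x, log_target, scale, rng)
        _set(weights, key, new_x)
        if accept is not None:
            a = accept.setdefault(key, [0, 0])
            a[0] += n_acc
            a[1] += L

    # root weights
    root_dependents = [f for f in factors if f.base == "root"]

    def root_prior(x):
        lp = dirichlet_logpdf(x, np.full(L, conc.alpha_root / L))
        if root_counts is not None and root_counts.sum() > 0:
            lp += float((root_counts * np.log(np.maximum(x, 1e-300))).sum())
        return lp

    sweep("root", root_prior, root_dependents)

    # hidden simplices, in chain order per node
    for f in factors:
        if f.target == "root" or f.target[0] != "nu":
            continue
        key = f.target
        prior_factor = f

        def nu_prior(x, pf=prior_factor, key=key):
            old = _get(weights, key)
            _set(weights, key, x)
            try:
                return _factor_logpdf(pf, weights, conc, dag)
            finally:
                _set(weights, key, old)

        dependents = [g for g in factors if g.base == key]
        sweep(key, nu_prior, dependents)
    return weights


def update_concentrations(
    dag: GroupDAG,
    conc: ConcentrationState,
    weights: WeightState,
    alpha0: float,
    rng: np.random.Generator,
    scales: dict,
    factors: list | None = None,
    accept: dict | None = None,
) -> ConcentrationState:
    """Log-scale random-walk Metropolis update of every concentration parameter.

    Each alpha targets its gamma-DAG conditional: its own gamma prior, the
    gamma terms of its children (whose shapes sum the parents' values), and
    every Dirichlet factor whose concentration involves it.
    """
    if factors is None:
        factors = build_factors(dag)
    L = weights.L
    nodes = [dag.root] + [j for j in dag.node_ids if j != dag.root]
    for j in nodes:
        involved = [f for f in factors if j in f.conc_nodes]

        def log_target(a_j):
            if a_j <= 0:
                return -np.inf
            old_root, old = conc.alpha_root, conc.alpha.get(j)
            if j == dag.root:
                conc.alpha_root = a_j
            else:
                conc.alpha[j] = a_j
            try:
                if j == dag.root:
                    lp = gamma_logpdf(a_j, alpha0)
                    lp += dirichlet_logpdf(
                        weights.beta_root, np.full(L, conc.alpha_root / L)
                    )
                else:
                    shape = sum(conc.of(dag, u) for u in dag.parents(j))
                    lp = gamma_logpdf(a_j, shape)
                for c in dag.children(j):
                    shape_c = sum(conc.of(dag, u) for u in dag.parents(c))
                    lp += gamma_logpdf(conc.of(dag, c), shape_c)
                for f in involved:
                    lp += _factor_logpdf(f, weights, conc, dag)
            finally:
                conc.alpha_root = old_root
                if old is not None:
                    conc.alpha[j] = old
            return lp

        current = conc.of(dag, j)
        scale = scales.get(j, 0.2)
        prop = float(np.exp(np.log(current) + scale * rng.normal()))
        lp_cur = log_target(current)
        lp_prop = log_target(prop)
        # log-normal proposal: Jacobian contributes log(prop/current)
        if np.log(rng.uniform()) < lp_prop - lp_cur + np.log(prop) - np.log(current):
            if j == dag.root:
                conc.alpha_root = prop
            else:
                conc.alpha[j] = prop
            if accept is not None:
                a = accept.setdefault(("alpha", j), [0, 0])
                a[0] += 1
                a[1] += 1
        elif accept is not None:
            a = accept.setdefault(("alpha", j), [0, 0])
            a[1] += 1
    return conc


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def _observation_loglik(
    data: GroupedDataset,
    dag: GroupDAG,
    weights: WeightState,
    atoms: AtomSet,
    z: AssignmentState,
) -> float:
    total = 0.0
    for j, xj in data.x.items():
        if xj.shape[0] == 0:
            continue
        zj = np.asarray(z.z[j])
        beta_j = np.maximum(weights.node_weights(dag, j), 1e-300)
        total += float(np.log(beta_j[zj]).sum())
        logf = mvn_logpdf_atoms(xj, atoms.means, atoms.covs)
        total += float(logf[np.arange(xj.shape[0]), zj].sum())
    return total


def _init_state(data, dag, g0, alpha0, L, init_mode, rng):
    conc = sample_concentrations(dag, alpha0, rng)
    weights = sample_weight_state(dag, conc, L, rng)
    N = data.n_total
    if init_mode == "kmeans" and N >= L:
        from sklearn.cluster import KMeans

        X, _ = data.pooled()
        km = KMeans(n_clusters=L, n_init=5, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(X)
        z = {}
        offset = 0
        for j in sorted(data.x):
            n_j = data.x[j].shape[0]
            z[j] = labels[offset : offset + n_j].astype(np.int64)
            offset += n_j
        assign = AssignmentState(z=z)
        atoms = update_atoms(data, assign, g0, L, rng)
    else:
        atoms = sample_atoms(g0, L, rng)
        z = {}
        for j in sorted(data.x):
            n_j = data.x[j].shape[0]
            beta_j = weights.node_weights(dag, j)
            z[j] = rng.choice(L, size=n_j, p=beta_j / beta_j.sum()).astype(np.int64)
        assign = AssignmentState(z=z)
    return conc, weights, atoms, assign


def run_gibbs(
    data: GroupedDataset,
    dag: GroupDAG,
    g0: NIWParams,
    alpha0: float,
    L: int,
    cfg: SamplerConfig,
) -> PosteriorSamples:
    """Run the Metropolis-within-blocked-Gibbs sampler.

    Chains run independently from distinct substreams of ``cfg.seed`` and are
    pooled after burn-in.  An empty dataset is allowed: the sampler then
    explores the prior (used for prior-recovery diagnostics).
    """
    if L < 2:
        raise ValueError("truncation level L must be >= 2")
    unknown = set(data.x) - set(dag.observed_nodes)
    if unknown:
        raise ValueError(f"data groups {sorted(unknown)} are not observed DAG nodes")

    factors = build_factors(dag)
    group_order = sorted(data.x)
    group_of = np.concatenate(
        [np.full(data.x[j].shape[0], j) for j in group_order]
    ) if group_order else np.empty(0, dtype=int)

    store: dict = {
        "z": [], "beta_root": [], "alpha_root": [], "loglik": [], "chain": [],
        "means": [], "covs": [],
        "beta": {j: [] for j in dag.node_ids if j != dag.root},
        "nu": {},
        "alpha": {j: [] for j in dag.node_ids if j != dag.root},
    }
    accept_totals: dict = {}

    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    for chain, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        conc, weights, atoms, assign = _init_state(
            data, dag, g0, alpha0, L, cfg.init_mode, rng
        )
        salt_scales = {key: cfg.salt_scale for key in _simplex_keys(dag)}
        alpha_scales = {j: cfg.alpha_rw_scale for j in dag.node_ids}
        accept: dict = {}
        batch_accept: dict = {}
        root_observed = dag.observed[dag.root] and dag.root in data.x

        for it in range(cfg.n_iter):
            if data.n_total:
                assign = update_assignments(data, weights, atoms, rng, dag)
            atoms = update_atoms(data, assign, g0, L, rng)
            for j in dag.node_ids:
                if j == dag.root:
                    continue
                counts = (
                    np.bincount(assign.z[j], minlength=L)
                    if j in data.x and data.x[j].shape[0]
                    else np.zeros(L)
                )
                k = dag.layer[j]
                top = weights.nu[(j, k)] if k >= 2 else weights.beta_root
                weights.beta[j] = update_node_weights(
                    counts, top, conc.of(dag, j), rng
                )
            root_counts = (
                np.bincount(assign.z[dag.root], minlength=L).astype(float)
                if root_observed and data.x[dag.root].shape[0]
                else None
            )
            sweep_accept: dict = {}
            update_hidden_weights(
                dag, weights, conc, rng, salt_scales,
                root_counts=root_counts, factors=factors, accept=sweep_accept,
            )
            update_concentrations(
                dag, conc, weights, alpha0, rng, alpha_scales,
                factors=factors, accept=sweep_accept,
            )
            for key, (na, np_) in sweep_accept.items():
                for d in (accept, batch_accept):
                    a = d.setdefault(key, [0, 0])
                    a[0] += na
                    a[1] += np_
            if cfg.adapt and it < cfg.burn_in and (it + 1) % _ADAPT_BATCH == 0:
                gain = min(0.25, 2.0 / np.sqrt(1 + it / _ADAPT_BATCH))
                for key, (na, np_) in batch_accept.items():
                    rate = na / max(np_, 1)
                    if key[0] == "alpha":
                        alpha_scales[key[1]] *= float(
                            np.exp(gain * (rate - _TARGET_ACCEPT))
                        )
                    else:
                        salt_scales[key] *= float(
                            np.exp(gain * (rate - _TARGET_ACCEPT))
                        )
                batch_accept = {}
            # floor((n_iter - burn_in)/thin) retained draws per chain
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == cfg.thin - 1:
                store["z"].append(
                    np.concatenate([assign.z[j] for j in group_order])
                    if group_order
                    else np.empty(0, dtype=np.int64)
                )
                store["beta_root"].append(weights.beta_root.copy())
                store["alpha_root"].append(conc.alpha_root)
                for j in store["beta"]:
                    store["beta"][j].append(weights.beta[j].copy())
                for key, v in weights.nu.items():
                    store["nu"].setdefault(key, []).append(v.copy())
                for j in store["alpha"]:
                    store["alpha"][j].append(conc.alpha[j])
                store["means"].append(atoms.means.copy())
                store["covs"].append(atoms.covs.copy())
                store["loglik"].append(
                    _observation_loglik(data, dag, weights, atoms, assign)
                )
                store["chain"].append(chain)
        for key, (na, np_) in accept.items():
            tot = accept_totals.setdefault(key, [0, 0])
            tot[0] += na
            tot[1] += np_

    rates = {k: (a / p if p else np.nan) for k, (a, p) in accept_totals.items()}
    return PosteriorSamples(
        z=np.array(store["z"], dtype=np.int64),
        group_of=group_of,
        beta_root=np.array(store["beta_root"]),
        beta={j: np.array(v) for j, v in store["beta"].items()},
        nu={k: np.array(v) for k, v in store["nu"].items()},
        alpha_root=np.array(store["alpha_root"]),
        alpha={j: np.array(v) for j, v in store["alpha"].items()},
        means=np.array(store["means"]),
        covs=np.array(store["covs"]),
        loglik=np.array(store["loglik"]),
        chain_id=np.array(store["chain"], dtype=int),
        accept_rates=rates,
        L=L,
        config=replace(cfg),
    )


def _simplex_keys(dag: GroupDAG):
    keys = ["root"]
    for j in dag.node_ids:
        if j == dag.root:
            continue
        for m in range(2, dag.layer[j] + 1):
            keys.append(("nu", j, m))
    return keys
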