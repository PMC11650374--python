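"""The graphical Dirichlet process (GDP) generative model.

The GDP links group-specific Dirichlet processes along a known graded DAG:
each group's random measure is a DP whose base measure is a mixture of its
parents' measures, with Dirichlet-distributed parent weights and a gamma-DAG
prior on the concentration parameters (each concentration is gamma with shape
equal to the sum of its parents' concentrations and unit rate).  Working with
the truncated (L-component) representation, the state of node j at layer k is
a chain of L-simplices: the root weights beta^(0), hidden simplices
nu_j^(k,m) for m = 2..k, and the node's mixing weights beta_j^(k), with

    beta^(0)          ~ Dir(alpha_root/L, ..., alpha_root/L)
    nu_j^(k,2)        ~ Dir(c_2  * beta^(0))
    nu_j^(k,m)        ~ Dir(c_m  * nu_j^(k,m-1))
    beta_j^(k)        ~ Dir(alpha_j * nu_j^(k,k))

where c_m sums the concentrations of the node's layer-(m-1) ancestors.
Mixture atoms phi_l = (mu_l, Sigma_l) are shared by all groups and drawn from
a normal-inverse-Wishart base measure; observations are Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import invwishart

from ._numeric import (
    dirichlet_logpdf,
    gamma_logpdf,
    mvn_logpdf_atoms,
    sample_dirichlet,
    sample_dirichlet_rows,
    sample_invwishart,
)
from .dag_core import GroupDAG, ancestors

__all__ = [
    "NIWParams",
    "ConcentrationState",
    "ParentMixtureWeights",
    "WeightState",
    "AtomSet",
    "AssignmentState",
    "GroupedDataset",
    "hidden_chain_concentrations",
    "sample_concentrations",
    "sample_parent_weights",
    "sample_weight_state",
    "sample_atoms",
    "niw_logpdf",
    "log_joint",
    "collapse_dirichlet_mixture",
]


@dataclass(frozen=True)
class NIWParams:
    """Normal-inverse-Wishart base measure for Gaussian (mean, covariance) atoms.

    ``Sigma ~ InvWishart(df, psi)`` and ``mu | Sigma ~ N(mean0, Sigma/kappa0)``.
    """

    mean0: np.ndarray
    kappa0: float
    psi: np.ndarray
    df: float

    def __post_init__(self):
        object.__setattr__(self, "mean0", np.asarray(self.mean0, dtype=float))
        object.__setattr__(self, "psi", np.asarray(self.psi, dtype=float))
        d = self.mean0.size
        if self.kappa0 <= 0:
            raise ValueError("kappa0 must be positive")
        if self.df <= d - 1:
            raise ValueError(f"df must exceed d-1={d - 1}")
        psi = self.psi
        if psi.shape != (d, d) or not np.allclose(psi, psi.T):
            raise ValueError("psi must be a symmetric d x d matrix")
        np.linalg.cholesky(psi)  # raises if not positive definite

    @property
    def d(self) -> int:
        return self.mean0.size


@dataclass
class ConcentrationState:
    """Concentration parameters of the gamma-DAG prior.

    ``alpha_root`` is the root's concentration; ``alpha[j]`` those of the
    non-root nodes; ``alpha0`` the fixed shape hyperparameter of the root.
    """

    alpha0: float
    alpha_root: float
    alpha: dict

    def of(self, dag: GroupDAG, node) -> float:
        return self.alpha_root if node == dag.root else self.alpha[node]


@dataclass
class ParentMixtureWeights:
    """Dirichlet-distributed weights mixing each node's parents' measures."""

    pi: dict  # node -> {parent: weight}


@dataclass
class WeightState:
    """Truncated mixing-weight state: root, hidden, and node simplices."""

    beta_root: np.ndarray  # (L,)
    nu: dict  # (node, m) -> (L,) for m = 2..layer(node)
    beta: dict  # non-root node -> (L,)
    L: int

    def node_weights(self, dag: GroupDAG, node) -> np.ndarray:
        """Mixing weights of a group; the root's weights are beta^(0)."""
        return self.beta_root if node == dag.root else self.beta[node]


@dataclass
class AtomSet:
    """Global Gaussian mixture atoms shared across groups."""

    means: np.ndarray  # (L, d)
    covs: np.ndarray  # (L, d, d)

    @property
    def L(self) -> int:
        return self.means.shape[0]


@dataclass
class AssignmentState:
    """Per-observation component indicators, one array per observed group."""

    z: dict  # node -> (n_j,) int array in [0, L)


@dataclass
class GroupedDataset:
    """Grouped real-valued observations: one (n_j, d) table per observed group."""

    x: dict  # node -> (n_j, d) array
    d: int = field(init=False)

    def __post_init__(self):
        self.x = {j: np.atleast_2d(np.asarray(v, dtype=float)) for j, v in self.x.items()}
        dims = {v.shape[1] for v in self.x.values() if v.size}
        if len(dims) > 1:
            raise ValueError(f"inconsistent feature dimensions across groups: {dims}")
        self.d = dims.pop() if dims else next(iter(self.x.values())).shape[1] if self.x else 0

    @property
    def n(self) -> dict:
        return {j: v.shape[0] for j, v in self.x.items()}

    @property
    def n_total(self) -> int:
        return sum(v.shape[0] for v in self.x.values())

    def pooled(self):
        """Stack all groups; returns (X, group_labels) in canonical group order."""
        groups = sorted(self.x)
        X = np.vstack([self.x[j] for j in groups]) if groups else np.empty((0, self.d))
        labels = np.concatenate(
            [np.full(self.x[j].shape[0], j) for j in groups]
        ) if groups else np.empty(0, dtype=int)
        return X, labels


def hidden_chain_concentrations(dag: GroupDAG, conc: ConcentrationState, node) -> list:
    """Concentrations c_m of the hidden chain of ``node``, for m = 2..k.

    c_m sums the concentrations of the node's generation-(k-m+1) ancestors,
    i.e. its ancestors sitting in layer m-1.  Empty for layer-1 nodes.
    """
    k = dag.layer[node]
    out = []
    for m in range(2, k + 1):
        anc = ancestors(dag, node, k - m + 1)
        out.append(sum(conc.of(dag, a) for a in anc))
    return out


_ALPHA_FLOOR = 1e-12


def sample_concentrations(
    dag: GroupDAG, alpha0: float, rng: np.random.Generator
) -> ConcentrationState:
    """Draw all concentrations from the gamma-DAG prior, in topological order.

    Draws are floored at a tiny positive value: the gamma chain can otherwise
    underflow to exact zero once a shape gets very small, which would break
    every downstream Dirichlet shape.
    """
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    alpha_root = max(float(rng.gamma(alpha0, 1.0)), _ALPHA_FLOOR)
    alpha: dict = {}
    conc = ConcentrationState(alpha0=alpha0, alpha_root=alpha_root, alpha=alpha)
    for j in dag.topological_order():
        if j == dag.root:
            continue
        shape = sum(conc.of(dag, u) for u in dag.parents(j))
        alpha[j] = max(float(rng.gamma(shape, 1.0)), _ALPHA_FLOOR)
    return conc


def sample_parent_weights(
    dag: GroupDAG, conc: ConcentrationState, rng: np.random.Generator
) -> ParentMixtureWeights:
    """Draw the parent-mixture weights pi_j ~ Dir(parents' concentrations)."""
    pi: dict = {}
    for j in dag.node_ids:
        pars = dag.parents(j)
        if not pars:
            continue
        shapes = np.array([conc.of(dag, u) for u in pars])
        w = sample_dirichlet(rng, shapes)
        pi[j] = dict(zip(pars, w))
    return ParentMixtureWeights(pi=pi)


def sample_weight_state(
    dag: GroupDAG, conc: ConcentrationState, L: int, rng: np.random.Generator
) -> WeightState:
    """Forward-sample the full truncated weight state along the DAG."""
    if L < 1:
        raise ValueError("truncation level L must be >= 1")
    beta_root = sample_dirichlet(rng, np.full(L, conc.alpha_root / L))
    nu: dict = {}
    beta: dict = {}
    for j in dag.topological_order():
        if j == dag.root:
            continue
        base = beta_root
        for m, c in enumerate(hidden_chain_concentrations(dag, conc, j), start=2):
            base = sample_dirichlet(rng, c * base)
            nu[(j, m)] = base
        beta[j] = sample_dirichlet(rng, conc.of(dag, j) * base)
    return WeightState(beta_root=beta_root, nu=nu, beta=beta, L=L)


def sample_node_weight_draws(
    dag: GroupDAG,
    conc: ConcentrationState,
    node,
    L: int,
    rng: np.random.Generator,
    size: int,
) -> np.ndarray:
    """Vectorized marginal draws of one node's weights via the truncated chain.

    Draws ``size`` independent replicates of (beta^(0), hidden chain,
    beta_node) and returns the node weights, shape (size, L).  The root node
    returns draws of beta^(0) itself.
    """
    base = sample_dirichlet(rng, np.full(L, conc.alpha_root / L), size=size)
    if node == dag.root:
        return base
    for c in hidden_chain_concentrations(dag, conc, node):
        base = sample_dirichlet_rows(rng, c * base)
    return sample_dirichlet_rows(rng, conc.of(dag, node) * base)


def sample_atoms(g0: NIWParams, L: int, rng: np.random.Generator) -> AtomSet:
    """Draw L i.i.d. (mean, covariance) atoms from the NIW base measure."""
    d = g0.d
    covs = sample_invwishart(rng, g0.df, g0.psi, size=L)
    chols = np.linalg.cholesky(covs / g0.kappa0)
    eps = rng.standard_normal((L, d))
    means = g0.mean0[None, :] + np.einsum("lde,le->ld", chols, eps)
    return AtomSet(means=means, covs=covs)


def niw_logpdf(mean: np.ndarray, cov: np.ndarray, g0: NIWParams) -> float:
    """Log density of one (mean, covariance) atom under the NIW base measure."""
    d = g0.d
    lp = invwishart.logpdf(cov, df=g0.df, scale=g0.psi)
    dev = mean - g0.mean0
    sign, logdet = np.linalg.slogdet(cov / g0.kappa0)
    maha = dev @ np.linalg.solve(cov / g0.kappa0, dev)
    return float(lp - 0.5 * (d * np.log(2 * np.pi) + logdet + maha))


def log_joint(
    dag: GroupDAG,
    conc: ConcentrationState,
    weights: WeightState,
    atoms: AtomSet,
    z: AssignmentState,
    data: GroupedDataset,
    g0: NIWParams,
) -> float:
    """Log density of the full truncated model at the given state.

    Sums the gamma-DAG terms, every Dirichlet factor of the weight chain, the
    NIW atom prior, and the categorical + Gaussian observation terms of all
    observed groups.
    """
    L = weights.L
    if atoms.L != L:
        raise ValueError("atoms and weights disagree on truncation level L")
    total = gamma_logpdf(conc.alpha_root, conc.alpha0)
    for j in dag.node_ids:
        if j == dag.root:
            continue
        shape = sum(conc.of(dag, u) for u in dag.parents(j))
        total += gamma_logpdf(conc.alpha[j], shape)
    total += dirichlet_logpdf(weights.beta_root, np.full(L, conc.alpha_root / L))
    for j in dag.node_ids:
        if j == dag.root:
            continue
        base = weights.beta_root
        for m, c in enumerate(hidden_chain_concentrations(dag, conc, j), start=2):
            total += dirichlet_logpdf(weights.nu[(j, m)], c * base)
            base = weights.nu[(j, m)]
        total += dirichlet_logpdf(weights.beta[j], conc.of(dag, j) * base)
    for l in range(L):
        total += niw_logpdf(atoms.means[l], atoms.covs[l], g0)
    for j, xj in data.x.items():
        if xj.shape[0] == 0:
            continue
        if xj.shape[1] != atoms.means.shape[1]:
            raise ValueError("data and atoms disagree on feature dimension")
        zj = np.asarray(z.z[j])
        bj = np.maximum(weights.node_weights(dag, j), 1e-300)
        total += float(np.log(bj[zj]).sum())
        logf = mvn_logpdf_atoms(xj, atoms.means, atoms.covs)
        total += float(logf[np.arange(xj.shape[0]), zj].sum())
    return float(total)


def collapse_dirichlet_mixture(
    alphas, rng: np.random.Generator, n_draws: int = 1
) -> dict:
    """Sample the Dirichlet mixture sum(pi_i * X_i) and its collapsed parameter.

    With independent X_i ~ Dir(alpha_i) and mixing weights
    pi ~ Dir(alpha_1., ..., alpha_L.) (row sums), the mixture sum(pi_i X_i)
    is again Dirichlet with parameter sum_i alpha_i.  Returns a dict with the
    drawn mixtures (``samples``, shape (n_draws, k)) and the collapsed
    parameter (``collapsed``), for empirical verification of the collapse.
    """
    A = np.atleast_2d(np.asarray(alphas, dtype=float))
    if np.any(A <= 0):
        raise ValueError("all concentration entries must be positive")
    Ldim, k = A.shape
    row_sums = A.sum(axis=1)
    if Ldim == 1:
        samples = sample_dirichlet(rng, A[0], size=n_draws)
    else:
        pi = sample_dirichlet(rng, row_sums, size=n_draws)  # (n_draws, Ldim)
        X = np.stack(
            [sample_dirichlet(rng, A[r], size=n_draws) for r in range(Ldim)], axis=1
        )  # (n_draws, Ldim, k)
        samples = np.einsum("ni,nik->nk", pi, X)
    return {"samples": samples, "collapsed": A.sum(axis=0)}
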