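"""Synthetic grouped datasets with the model's dependence structure.

The generator mirrors the benchmark design used throughout the package's
tests: eight experimental groups linked by a three-layer DAG (a baseline
group, three one-factor groups, three two-factor groups, and one three-
factor group), observations drawn per group from a four-component mixture of
bivariate Gaussians with a group-specific covariance, and mixture weights
drawn from the truncated GDP itself (concentrations from the gamma-DAG prior
with alpha0 = 5).  Presets cover the benchmark's sample-size rows plus a
low-separation "hard" variant and a fork (exchangeable-groups) topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dag_core import GroupDAG, build_dag
from .gdp_prior import (
    AssignmentState,
    ConcentrationState,
    GroupedDataset,
    WeightState,
    sample_concentrations,
    sample_weight_state,
)

__all__ = [
    "EIGHT_GROUP_EDGES",
    "TABLE_SIZES",
    "SimulationDesign",
    "eight_group_dag",
    "fork_dag",
    "preset_designs",
    "simulate_grouped_data",
]

# Baseline -> main effects -> two-way interactions -> three-way interaction
EIGHT_GROUP_EDGES = (
    (1, 2), (1, 3), (1, 4),
    (2, 5), (4, 5), (2, 6), (3, 6), (3, 7), (4, 7),
    (5, 8), (6, 8), (7, 8),
)

TABLE_SIZES = {
    "small": (40, 30, 30, 35, 25, 30, 25, 30),
    "moderate": (80, 70, 70, 75, 83, 88, 92, 88),
    "large": (150, 160, 180, 170, 155, 175, 185, 145),
    "unbalanced": (350, 30, 40, 45, 25, 25, 35, 35),
}

# Four well-separated component means (pairwise distance >= 5 within-cluster
# sd for unit-scale covariances); the "hard" preset shrinks them to ~2 sd.
_MEANS_SEPARATED = np.array([[-6.0, -6.0], [-6.0, 6.0], [6.0, -6.0], [6.0, 6.0]])
_MEANS_HARD = _MEANS_SEPARATED / 4.0

# One covariance per group: distinct, but modest heterogeneity.  Atoms
# (mean and covariance) are shared by all groups in the model, so strongly
# group-varying within-cluster covariances would make every shared atom
# misspecified for its pooled cluster and push the posterior toward
# covering one true cluster with several near-duplicate components.
_GROUP_COVS = {
    1: np.array([[1.00, 0.05], [0.05, 0.95]]),
    2: np.array([[1.05, -0.08], [-0.08, 0.92]]),
    3: np.array([[0.93, 0.06], [0.06, 1.08]]),
    4: np.array([[1.02, 0.00], [0.00, 0.90]]),
    5: np.array([[0.96, 0.10], [0.10, 1.04]]),
    6: np.array([[1.08, -0.05], [-0.05, 0.94]]),
    7: np.array([[0.91, -0.06], [-0.06, 0.99]]),
    8: np.array([[1.04, 0.08], [0.08, 1.06]]),
}


def eight_group_dag() -> GroupDAG:
    """The three-layer, eight-group experimental DAG (all groups observed)."""
    return build_dag(EIGHT_GROUP_EDGES)


def fork_dag(n_children: int = 8) -> GroupDAG:
    """A hidden root with exchangeable observed children (the HDP topology)."""
    edges = [(0, j) for j in range(1, n_children + 1)]
    return build_dag(edges, observed={0: False})


@dataclass
class SimulationDesign:
    """Everything needed to draw one grouped dataset with known truth."""

    dag: GroupDAG
    alpha0: float
    n_components_true: int
    means_true: np.ndarray  # (n_components_true, d)
    covs_true: dict  # group -> (d, d) positive-definite
    sizes: dict  # group -> n_j
    seed: int = 0
    name: str = field(default="custom")


def preset_designs(name: str) -> SimulationDesign:
    """Named benchmark designs.

    ``small`` / ``moderate`` / ``large`` / ``unbalanced`` use the eight-group
    DAG with the corresponding sample-size rows and well-separated
    components; ``hard`` uses the small sizes with ~2-sd separation;
    ``fork_hdp`` places the small sizes on a fork (hidden root, eight
    exchangeable children).
    """
    if name in TABLE_SIZES:
        dag = eight_group_dag()
        sizes = dict(zip(range(1, 9), TABLE_SIZES[name]))
        means = _MEANS_SEPARATED
        covs = dict(_GROUP_COVS)
    elif name == "hard":
        dag = eight_group_dag()
        sizes = dict(zip(range(1, 9), TABLE_SIZES["small"]))
        means = _MEANS_HARD
        covs = dict(_GROUP_COVS)
    elif name == "fork_hdp":
        dag = fork_dag(8)
        sizes = dict(zip(range(1, 9), TABLE_SIZES["small"]))
        means = _MEANS_SEPARATED
        covs = dict(_GROUP_COVS)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return SimulationDesign(
        dag=dag,
        alpha0=5.0,
        n_components_true=4,
        means_true=means.copy(),
        covs_true=covs,
        sizes=sizes,
        name=name,
    )


def simulate_grouped_data(design: SimulationDesign):
    """Draw one grouped dataset plus its full generative ground truth.

    Concentrations come from the gamma-DAG prior, mixture weights from the
    truncated weight chain at the true number of components, true indicators
    from per-group multinomials, and observations from Gaussians with the
    indicated component mean and the group's covariance.

    Returns ``(data, truth, weights, conc)``.
    """
    rng = np.random.default_rng(design.seed)
    dag = design.dag
    conc = sample_concentrations(dag, design.alpha0, rng)
    weights = sample_weight_state(dag, conc, design.n_components_true, rng)
    x: dict = {}
    z: dict = {}
    d = design.means_true.shape[1]
    for j in dag.observed_nodes:
        n_j = int(design.sizes.get(j, 0))
        beta_j = weights.node_weights(dag, j)
        z_j = rng.choice(design.n_components_true, size=n_j, p=beta_j / beta_j.sum())
        cov = design.covs_true[j]
        chol = np.linalg.cholesky(cov)
        eps = rng.standard_normal((n_j, d))
        x[j] = design.means_true[z_j] + eps @ chol.T
        z[j] = z_j.astype(np.int64)
    data = GroupedDataset(x=x)
    truth = AssignmentState(z=z)
    return data, truth, weights, conc
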