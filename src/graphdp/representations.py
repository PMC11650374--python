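"""Alternative constructions of the graphical Dirichlet process.

Besides the finite truncated representation used for inference, the GDP
admits three equivalent constructions that this module implements as prior
samplers, chiefly to cross-validate the finite representation:

* the *stick-breaking* construction of a single DP's weights (GEM);
* the *hypergraph chain*: a node at layer k is a DP whose base is itself a
  DP over the summed concentrations of the node's generation-1 ancestors,
  nested down generation by generation until the root measure;
* the *family-owned restaurant process*, the predictive (urn) construction:
  customers sit at tables within each group's restaurant, new tables order
  their dish through a chain of hyper-restaurants (one per ancestor
  generation), and the root relays dishes from the global menu.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dag_core import GroupDAG, ancestors
from .gdp_prior import ConcentrationState

__all__ = [
    "HypergraphChain",
    "RestaurantState",
    "stick_break",
    "hypergraph_chain",
    "sample_weights_via_hypergraph",
    "restaurant_sim",
    "prior_cocluster_probability",
]


def stick_break(alpha: float, L: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated GEM weights: L-1 Beta(1, alpha) sticks, remainder to the last.

    The closure convention (all remaining mass on coordinate L) makes the
    result an exact point of the simplex, comparable to the finite states.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if L < 1:
        raise ValueError("L must be >= 1")
    w = np.empty(L)
    remaining = 1.0
    for k in range(L - 1):
        v = rng.beta(1.0, alpha)
        w[k] = v * remaining
        remaining *= 1.0 - v
    w[L - 1] = remaining
    return w


@dataclass(frozen=True)
class HypergraphChain:
    """Nested-DP concentration sequence of one node, anchored at the root.

    ``concentrations[0]`` is the node's own concentration; entry g (g >= 1)
    sums the concentrations of the node's generation-g ancestors.  The chain
    has exactly ``layer(node)`` entries; its base is the root measure.
    """

    node: int
    concentrations: tuple
    labels: tuple

    def __len__(self) -> int:
        return len(self.concentrations)


def hypergraph_chain(
    dag: GroupDAG, conc: ConcentrationState, node
) -> HypergraphChain:
    """The nested-DP chain of ``node``: own concentration, then ancestor sums."""
    if node not in dag.layer:
        raise KeyError(f"unknown node {node}")
    k = dag.layer[node]
    if k < 1:
        raise ValueError("the root has no hypergraph chain")
    concs = [conc.of(dag, node)]
    labels = [f"node {node}"]
    for g in range(1, k):
        anc = ancestors(dag, node, g)
        concs.append(sum(conc.of(dag, a) for a in anc))
        labels.append(f"generation-{g} ancestors {tuple(sorted(anc))}")
    return HypergraphChain(node=node, concentrations=tuple(concs), labels=tuple(labels))


def _dirichlet_rows(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet draws for a matrix of concentration vectors.

    Gamma variates are formed in log space (boost identity for shapes < 1)
    so rows with very small concentrations do not collapse to zeros.
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    with np.errstate(over="ignore", divide="ignore"):
        log_g = np.log(rng.gamma(alpha + 1.0)) + np.log1p(-rng.uniform(size=alpha.shape)) / alpha
    log_g -= log_g.max(axis=-1, keepdims=True)
    g = np.maximum(np.exp(log_g), 1e-300)  # keep chained links strictly positive
    return g / g.sum(axis=-1, keepdims=True)


def sample_weights_via_hypergraph(
    chain: HypergraphChain,
    beta_root: np.ndarray,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Sample a node's truncated weights by walking the hypergraph chain.

    Starting from the root weights, each chain link (deepest first) draws a
    Dirichlet whose concentration vector is the link's total concentration
    times the previous simplex; the final link uses the node's own
    concentration.  With ``size`` given, ``beta_root`` may be a single
    simplex (shared root) or a (size, L) array of root draws.

    Returns a (L,) simplex, or (size, L) when ``size`` is given.
    """
    beta_root = np.asarray(beta_root, dtype=float)
    single = size is None
    base = np.atleast_2d(beta_root)
    if not single and base.shape[0] == 1:
        base = np.repeat(base, size, axis=0)
    for c in reversed(chain.concentrations):
        base = _dirichlet_rows(rng, c * base)
    return base[0] if single else base


# ---------------------------------------------------------------------------
# Family-owned restaurant process
# ---------------------------------------------------------------------------


@dataclass
class RestaurantState:
    """Full bookkeeping of one realization of the family-owned restaurant process.

    ``tables[j]`` lists ``[n_customers, dish]`` per table of restaurant j;
    ``hyper[(j, g)]`` maps dish -> number of hyper-tables at the node's
    generation-g hyper-restaurant (g = 1..layer(j)-1); ``root_tables`` lists
    ``[n_customers, dish]`` at the root restaurant (zero-customer tables are
    opened by dish requests relayed from below); ``customer_dishes[j]`` gives
    each customer's dish in seating order; ``dishes`` is the global menu in
    order of first serving.
    """

    tables: dict = field(default_factory=dict)
    hyper: dict = field(default_factory=dict)
    root_tables: list = field(default_factory=list)
    customer_dishes: dict = field(default_factory=dict)
    dishes: list = field(default_factory=list)

    def n_tables(self, node) -> int:
        return len(self.tables[node])

    def dish_counts(self, node) -> dict:
        """m_jl: number of tables of restaurant ``node`` serving each dish."""
        out: dict = {}
        for _, dish in self.tables[node]:
            out[dish] = out.get(dish, 0) + 1
        return out

    def n_root_tables(self) -> int:
        return len(self.root_tables)

    def root_dish_counts(self) -> dict:
        out: dict = {}
        for _, dish in self.root_tables:
            out[dish] = out.get(dish, 0) + 1
        return out


def restaurant_sim(
    dag: GroupDAG,
    conc: ConcentrationState,
    n_customers: dict,
    rng: np.random.Generator,
    g0_labeler=None,
) -> RestaurantState:
    """Simulate the family-owned restaurant process for given customer counts.

    Customers are seated sequentially, nodes in topological order.  Within a
    restaurant a customer joins table t with probability proportional to its
    occupancy or opens a new table with probability proportional to the
    node's concentration; a new table's dish is resolved through the node's
    hyper-restaurants (Polya urns over per-dish table counts, one per
    ancestor generation) and ultimately at the root, where genuinely new
    dishes are drawn from the global menu via ``g0_labeler``.

    The root node, when observed, seats its own customers as a plain Chinese
    restaurant process over the root tables (its dish requests from below
    still follow the urn over per-dish root-table counts).
    """
    if g0_labeler is None:
        counter = iter(range(10**9))
        g0_labeler = lambda rng: next(counter)  # noqa: E731

    state = RestaurantState()
    state.tables = {j: [] for j in dag.node_ids if j != dag.root}
    state.customer_dishes = {j: [] for j in dag.node_ids}

    def new_dish() -> object:
        dish = g0_labeler(rng)
        state.dishes.append(dish)
        return dish

    def draw_from_root() -> object:
        """Dish request at the root level (urn over per-dish root-table counts)."""
        counts = state.root_dish_counts()
        dishes = list(counts)
        weights = [counts[d] for d in dishes] + [conc.alpha_root]
        total = sum(weights)
        u = rng.uniform() * total
        acc = 0.0
        for d, w in zip(dishes, weights[:-1]):
            acc += w
            if u < acc:
                state.root_tables.append([0, d])
                return d
        d = new_dish()
        state.root_tables.append([0, d])
        return d

    def draw_from_hyper(j: int, g: int, k: int) -> object:
        """Dish request at the generation-g hyper-restaurant of node j."""
        if g > k - 1:
            return draw_from_root()
        counts = state.hyper.setdefault((j, g), {})
        c = sum(conc.of(dag, a) for a in ancestors(dag, j, g))
        dishes = list(counts)
        weights = [counts[d] for d in dishes] + [c]
        total = sum(weights)
        u = rng.uniform() * total
        acc = 0.0
        chosen = None
        for d, w in zip(dishes, weights[:-1]):
            acc += w
            if u < acc:
                chosen = d
                break
        if chosen is None:
            chosen = draw_from_hyper(j, g + 1, k)
        counts[chosen] = counts.get(chosen, 0) + 1
        return chosen

    for j in dag.topological_order():
        n_j = int(n_customers.get(j, 0))
        if n_j and not dag.observed[j]:
            raise ValueError(f"hidden node {j} cannot seat customers")
        if j == dag.root:
            for _ in range(n_j):
                weights = [t[0] for t in state.root_tables] + [conc.alpha_root]
                total = sum(weights)
                u = rng.uniform() * total
                acc = 0.0
                seated = False
                for t, w in zip(state.root_tables, weights[:-1]):
                    acc += w
                    if u < acc:
                        t[0] += 1
                        state.customer_dishes[j].append(t[1])
                        seated = True
                        break
                if not seated:
                    d = new_dish()
                    state.root_tables.append([1, d])
                    state.customer_dishes[j].append(d)
            continue
        k = dag.layer[j]
        alpha_j = conc.of(dag, j)
        for _ in range(n_j):
            tables = state.tables[j]
            weights = [t[0] for t in tables] + [alpha_j]
            total = sum(weights)
            u = rng.uniform() * total
            acc = 0.0
            seated = False
            for t, w in zip(tables, weights[:-1]):
                acc += w
                if u < acc:
                    t[0] += 1
                    state.customer_dishes[j].append(t[1])
                    seated = True
                    break
            if not seated:
                d = draw_from_hyper(j, 1, k)
                tables.append([1, d])
                state.customer_dishes[j].append(d)
    return state


def prior_cocluster_probability(
    dag: GroupDAG,
    conc: ConcentrationState,
    node_pair: tuple,
    rng: np.random.Generator,
    n_reps: int = 10_000,
) -> float:
    """Monte-Carlo prior probability that two groups' first customers share a dish.

    For a pair ``(a, a)`` the probability that the node's first two customers
    share a dish is estimated instead.  Summarizes how strongly the DAG lets
    nearby groups share mixture components a priori.
    """
    a, b = node_pair
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    counts = {a: 2} if a == b else {a: 1, b: 1}
    hits = 0
    for _ in range(n_reps):
        st = restaurant_sim(dag, conc, counts, rng)
        if a == b:
            hits += st.customer_dishes[a][0] == st.customer_dishes[a][1]
        else:
            hits += st.customer_dishes[a][0] == st.customer_dishes[b][0]
    return hits / n_reps
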