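"""Sample the GDP prior and cross-check its constructions against each other.

The truncated weight chain, the hypergraph (nested-DP) chain, and the
family-owned restaurant process are three routes to the same prior.  This
example draws from each and prints summaries showing their agreement.
"""

import numpy as np

import graphdp as gdp

rng = np.random.default_rng(7)
dag = gdp.eight_group_dag()

conc = gdp.sample_concentrations(dag, alpha0=5.0, rng=rng)
print("concentrations:", {j: round(conc.of(dag, j), 2) for j in dag.node_ids})

# route 1: the truncated chain; route 2: the hypergraph chain
L, n = 5, 20_000
a = gdp.sample_node_weight_draws(dag, conc, node=8, L=L, rng=rng, size=n)
chain = gdp.hypergraph_chain(dag, conc, 8)
print("hypergraph chain of node 8:", [round(c, 2) for c in chain.concentrations])
from graphdp._numeric import sample_dirichlet

root = sample_dirichlet(rng, np.full(L, conc.alpha_root / L), size=n)
b = gdp.sample_weights_via_hypergraph(chain, root, rng, size=n)
print("coordinate means, truncated chain :", np.round(a.mean(axis=0), 3))
print("coordinate means, hypergraph chain:", np.round(b.mean(axis=0), 3))
# both are ~1/L = 0.2: the node's weights center on the root weights

# route 3: the restaurant process; expected root tables follow the CRP sum
state = gdp.restaurant_sim(dag, conc, {j: 10 for j in range(1, 9)}, rng)
print("global dishes created:", len(state.dishes))
print("tables per group:", {j: state.n_tables(j) for j in dag.non_root_nodes})
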