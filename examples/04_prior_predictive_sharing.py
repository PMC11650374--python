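"""How strongly do related groups share clusters a priori?

Two probes: (i) the restaurant-process probability that two groups' first
observations share a mixture component (anchored at the root urn, it equals
1/(1 + alpha_root) for any pair); (ii) the correlation between sibling
groups' mixing-weight vectors, which reflects the graded sharing that the
concentration chain induces.
"""

import numpy as np

import graphdp as gdp

dag = gdp.eight_group_dag()
rng = np.random.default_rng(3)

conc = gdp.ConcentrationState(
    alpha0=1.0, alpha_root=1.0, alpha={j: 1.0 for j in dag.non_root_nodes}
)
for pair in [(5, 6), (2, 8)]:
    p = gdp.prior_cocluster_probability(dag, conc, pair, rng, n_reps=20_000)
    print(f"P(first customers of {pair} share a dish) = {p:.3f} "
          f"(root urn gives 1/(1+alpha_root) = 0.5)")

# weight-level sharing: siblings correlate through their common ancestry
draws = np.empty((2000, 2))
for i in range(2000):
    c = gdp.sample_concentrations(dag, 5.0, rng)
    w = gdp.sample_weight_state(dag, c, 4, rng)
    draws[i] = w.beta[5][0], w.beta[6][0]
r = np.corrcoef(draws.T)[0, 1]
print(f"corr(beta_5, beta_6) first coordinate over the prior: {r:.2f} (> 0)")
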