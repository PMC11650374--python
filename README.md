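# graphdp

Bayesian nonparametric clustering of grouped data whose groups are **not
exchangeable** but linked by a known directed acyclic graph (DAG) — for
example experimental designs where a baseline condition branches into
one-factor, two-factor, and three-factor treatment groups, each group
holding its own observations (in the motivating setting, 2-D embedding
coordinates of single cells per experimental group).

The model is a *graphical Dirichlet process* (GDP) mixture: every group
`j` carries a random measure `G_j`, the root group follows
`G_root ~ DP(α_root, G0)`, and every other group is a Dirichlet process
whose base measure is a mixture of its parents' measures,

```
G_j | α_j, {G_l : l ∈ pa(j)}  ~  DP(α_j, Σ_l π_jl G_l),
π_j ~ Dir(α_l : l ∈ pa(j)),        α_j ~ Gamma(Σ_l∈pa(j) α_l, 1).
```

All groups share one global set of Gaussian atoms drawn from a
normal-inverse-Wishart base measure, so clusters are identified *across*
groups while mixing weights stay group-specific, and the joint law respects
the Markov property of the DAG.  The hierarchical DP is the special case of
a fork (one hidden root, exchangeable children).

The package provides:

* `dag_core` — graded layered DAGs over groups: validation, hidden-root
  augmentation, generation-`g` ancestors, Markov blankets;
* `gdp_prior` — the full generative model and its truncated (level-`L`)
  weight chain;
* `representations` — the equivalent constructions (stick-breaking,
  nested-DP "hypergraph" chain, family-owned restaurant process), used as
  cross-checking oracles;
* `gibbs_sampler` — a Metropolis-within-blocked-Gibbs posterior sampler:
  conjugate updates for indicators, atoms, and node weights; logit-simplex
  (SALT-style) Metropolis for root/hidden weights; log-scale random walks
  for concentrations;
* `estimation` — posterior similarity, least-squares (Dahl) partition,
  adjusted Rand index, internal validation indices, k-means baseline;
* `synthetic_data` — the benchmark simulation designs (8-group DAG, four
  bivariate Gaussian components, named sample-size presets);
* `cli_io` — file I/O plus a thin `gdp` command-line tool
  (`simulate`, `fit`, `evaluate`, `oracle`).

See `docs/methods.md` for the model, sampler, and design notes, and
`examples/` for short narrative scripts, one per capability.

## Worked example

`examples/03_fit_benchmark_simulation.py` simulates the benchmark "small"
design (8 groups on the three-layer DAG, 245 bivariate points from 4
Gaussian components, weights drawn from the GDP itself with α0 = 5), fits
the mixture with L = 10, and scores the least-squares clustering:

```
$ python examples/03_fit_benchmark_simulation.py
simulated 245 points in 8 groups, d = 2
retained 400 draws; final log-likelihood -985.3
ARI vs truth: 0.999
silhouette 0.824, Calinski-Harabasz 1041.1, Davies-Bouldin 0.537
k-means (k = 10) ARI: 0.196
```

An adjusted Rand index of 0.999 means the recovered partition is
essentially identical to the simulated truth; k-means at the same
`k = L = 10` fragments the four true clusters (ARI 0.196).  The silhouette
(0.82) and Davies-Bouldin (0.54) values reflect tight, well-separated
clusters at this preset's ≥ 5-sd component separation.

The same fit from a shell (`dag.json` holds the edge list, e.g.
`{"edges": [[1,2],[1,3],[1,4],[2,5],[4,5],[2,6],[3,6],[3,7],[4,7],[5,8],[6,8],[7,8]]}`):

```bash
gdp simulate --preset small --seed 1 --out data.csv --truth truth.csv
gdp fit --data data.csv --dag dag.json --L 10 --alpha0 5 \
        --iters 3000 --burnin 1000 --thin 5 --seed 2 --out run/
gdp evaluate --labels run/labels.csv --truth truth.csv --data data.csv \
        --out metrics.json
```

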