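# Methods

## The model

`graphdp` clusters observations that fall into groups linked by a known
directed acyclic graph (DAG).  Groups are nodes; an edge points from a
parent group to a group derived from it.  Each group `j` carries a random
probability measure `G_j` and the joint law factorizes over the DAG: the
root's measure is a Dirichlet process, `G_root ~ DP(alpha_root, G0)`, and
every other node is a DP whose base measure is a convex mixture of its
parents' measures,

    G_j | alpha_j, {G_l : l in pa(j)}  ~  DP(alpha_j, sum_l pi_jl G_l).

Because DP draws are discrete, all groups share one global set of atoms;
clusters are therefore comparable across groups, while each group keeps its
own mixing weights.  Two hyperpriors complete the model:

* **parent-mixture weights** `pi_j ~ Dirichlet(alpha of each parent)` — a
  parent with higher precision (concentration) contributes more;
* **gamma-DAG concentrations** — `alpha_root ~ Gamma(alpha0, 1)` and each
  `alpha_j ~ Gamma(sum of its parents' alphas, 1)`.

The DAG must be *graded* (every edge connects consecutive layers) because
all recursions are layer-wise; `build_dag` rejects anything else, and a
multi-root input is augmented with a single hidden parent, which is the
standard reduction to a unique root.  The hierarchical DP is exactly the
fork special case (one hidden root, exchangeable children).

### Equivalent constructions

Three alternative constructions are implemented in `representations` and
used as cross-validation oracles for the finite model:

* **hypergraph chain** — marginally, a layer-`k` node is a chain of nested
  DPs whose concentrations are the node's own alpha followed by the summed
  alphas of each ancestor generation, anchored at the root measure;
* **stick-breaking** — weight-space version of the same chain (GEM at the
  root, Dirichlet links below); truncation assigns all remaining stick mass
  to the last coordinate so states are exact simplex points;
* **family-owned restaurant process** — the predictive urn: customers join
  tables proportionally to occupancy or open new tables proportionally to
  the node's alpha; a new table's dish is resolved through one Pólya urn per
  ancestor generation (per-node hyper-restaurants over per-dish table
  counts) and ultimately at the root urn, where new dishes come from the
  global menu.  With a hidden root this reduces to the Chinese restaurant
  franchise on a fork.  For an observed root we seat the root's own
  customers as a plain CRP over root tables — the omitted observed-root
  analog of the construction, implemented as our declared reading.

A structural consequence worth knowing: the per-node hyper-urns are empty
when a group's *first* customer arrives, so its dish request falls straight
through to the root urn.  First-observation cluster sharing between any two
groups therefore equals `1/(1 + alpha_root)` regardless of their distance
in the DAG; graded proximity effects enter through the correlated
concentrations and the weight chain, not through first-customer dishes.

## The finite representation and the sampler

Inference uses the truncated (level `L`) representation: root weights
`beta^(0) ~ Dir(alpha_root/L, ..., alpha_root/L)`, per-node hidden simplices

    nu_j^(k,2) ~ Dir(c_2 beta^(0)),   ...,   nu_j^(k,k) ~ Dir(c_k nu_j^(k,k-1)),
    beta_j     ~ Dir(alpha_j nu_j^(k,k)),

with `c_m` the summed alphas of the node's layer-(m-1) ancestors, plus
global Gaussian atoms `phi_l = (mu_l, Sigma_l) ~ NIW(m0, kappa0, Psi, df)`
and indicators `z_ji ~ beta_j`.

The Metropolis-within-blocked-Gibbs cycle is, per sweep:

1. `z` — exact categorical draws (log-space, Gumbel-max);
2. atoms — exact normal-inverse-Wishart conjugate draws, pooled across
   groups; empty components redraw from the prior (cluster birth);
3. each node's `beta_j` — exact Dirichlet conjugate draw
   `Dir(alpha_j nu + counts)`;
4. `beta^(0)` and every `nu` — per-coordinate logit-simplex ("SALT")
   Metropolis.  A coordinate moves by a Gaussian step on the logit scale and
   the rest rescale proportionally; the Hastings factor is the exact
   Jacobian `log[x'_c(1-x'_c)] - log[x_c(1-x_c)] + (L-2) log[(1-x'_c)/(1-x_c)]`.
   The full conditional of a simplex is its own Dirichlet prior factor times
   every Dirichlet factor in which it appears as the base (plus the root
   group's multinomial counts when the root is observed);
5. each alpha — log-scale Gaussian random-walk Metropolis against its
   gamma-DAG conditional times all Dirichlet factors whose concentration
   contains it.

The update order groups the conjugate blocks first; since the exact sampler
layout is an open design point, this order is our choice.  Proposal scales
adapt toward 0.44 acceptance in batches of 50 during burn-in only
(Robbins–Monro on the log scale, gain decaying as 1/sqrt(batch)), frozen
afterwards so the post-burn-in chain is a fixed Markov kernel.  Chains run
from independent `SeedSequence` substreams and are pooled after burn-in.
With an empty dataset every conditional reduces to the prior; this prior
mode is exercised by the prior-recovery test.

Correctness evidence beyond unit tests: on a tiny fork model (three
observations, two components, fixed atoms and alphas) the sampler's
assignment posterior matches brute-force enumeration of all assignments to
four decimal places, and on a fork DAG the posterior similarity matrix
matches an independently written truncated-HDP sampler entrywise within
0.05.

### Numerical choices

* Dirichlet draws use log-space gammas with the shape-boost identity
  `Gamma(a) = Gamma(a+1) U^(1/a)` so shapes as small as `alpha/L` (or the
  products `c_m * nu` with tiny base entries) never collapse to exact
  zeros; results are floored at 1e-300 and renormalized.
* Concentration draws are floored at 1e-12: the gamma chain can otherwise
  underflow to exact zero once one shape becomes very small.
* The SALT proposal renormalizes after rescaling; without this the simplex
  sum drifts multiplicatively over accepted moves.
* Inverse-Wishart draws use the Bartlett decomposition; Gaussian log
  densities over atoms are evaluated with batched Cholesky factorizations.
* Dahl ties break toward the earliest retained draw.

## Point estimation and evaluation

Atoms are global, so all observations are pooled: the posterior similarity
matrix (PSM) holds pairwise co-clustering frequencies over retained draws,
and the reported partition is the retained draw whose 0/1 association
matrix minimizes the squared Frobenius distance to the PSM (least-squares
criterion, searched over retained draws as is standard).  Agreement with a
reference labeling uses the Hubert–Arabie adjusted Rand index; internal
quality uses Calinski–Harabasz, Davies–Bouldin, and silhouette on the
pooled observations (whether to pool or score per group is unstated in the
problem setting; we pool and say so).  A pooled k-means with `k = L` is the
non-Bayesian baseline.

## Synthetic data

The generator reproduces the benchmark design: eight observed groups on a
three-layer DAG (baseline; three one-factor groups; three two-factor
groups; one three-factor group), four bivariate Gaussian components,
concentrations from the gamma-DAG prior with `alpha0 = 5`, mixture weights
from the truncated chain itself (truncated at the true component count, 4),
indicators from per-group multinomials, and observations from the
component mean with a group-specific covariance.  Size presets `small`,
`moderate`, `large`, and `unbalanced` follow the benchmark's sample-size
rows (e.g. small = 40, 30, 30, 35, 25, 30, 25, 30).

The exact component means and covariances of the original study are not
published, so they are declared package constants: means at
`(±6, ±6)` (pairwise separation at least 5 within-cluster standard
deviations) with per-group covariances that are distinct but modestly
heterogeneous (identity-like, correlations within ±0.10).  The modesty is
deliberate: atoms — covariance included — are shared by all groups, so
strongly group-varying true covariances make every shared atom
misspecified for its pooled cluster, and the exact posterior then prefers
covering one true cluster with several near-duplicate atoms, which no
correct sampler can undo.  The `hard` preset divides the means by 4
(~2–3 sd separation) to preserve the easy/hard contrast; `fork_hdp` puts
the same sizes on a fork for exchangeable-group comparisons.

What the generator does *not* emulate: single-cell count structure, library
size effects, or the geometry of nonlinear embeddings.  Passing tests show
the method recovers structure of its own generative form at embedding
scale; they say nothing about upstream preprocessing of real data.

## Behavior worth knowing (and limitations)

* **Concentrations grow along the DAG.**  Shapes sum over parents, so the
  prior mean of `alpha_j` is `alpha0` times the number of directed root
  paths to `j` (30 for the deepest benchmark group at `alpha0 = 5`), and
  `alpha_j` is the effective prior sample size of the group's weights.
  With well-separated components the likelihood dominates and recovery is
  excellent; when components overlap heavily, deep groups' weights become
  prior-dominated, the fit spreads mass over extra truncation components,
  and the GDP can over-cluster where a fork (HDP) fit, whose per-group
  concentration stays near `alpha0`, does not.  The low-separation
  comparison test documents this regime honestly.
* With `L` well above the true component count, extra components are kept
  empty by the sparse root prior `Dir(alpha_root/L)`; this is the standard
  truncation convention and mirrors the benchmark's `L = 10`.
* Problem sizes used by the test-suite and the acceptance script — 3,000
  sweeps (1,000 burn-in, thin 5) for the benchmark recovery runs, 1,000
  sweeps for the low-separation replicates, 10,000-sweep four-chain runs
  for the HDP-equivalence check, and 10^5-draw Monte Carlo for closed-form
  checks — are the package's chosen desk-scale defaults; the full-scale
  protocol (15,000 sweeps, 5,000 burn-in, thin 10) is a `SamplerConfig`
  away.
* Non-graded DAGs (e.g. autoregressive lag-2 structures) are rejected
  rather than approximated: the layer-wise recursions are defined only for
  graded DAGs and we do not guess a generalization.
* The restaurant representation is a prior/predictive simulator and test
  oracle only; the production posterior path is the truncated blocked
  sampler.
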