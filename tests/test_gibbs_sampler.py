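"""Unit-level correctness of the Gibbs sampler blocks and driver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from graphdp import (
    AssignmentState,
    ConcentrationState,
    GroupedDataset,
    NIWParams,
    SamplerConfig,
    WeightState,
    adjusted_rand,
    build_dag,
    dahl_estimate,
    loglik_trace,
    run_gibbs,
    salt_propose,
    sample_atoms,
    update_assignments,
    update_atoms,
    update_hidden_weights,
    update_node_weights,
)
from graphdp._numeric import sample_dirichlet
from graphdp.gibbs_sampler import _niw_posterior, salt_metropolis_sweep

G0_2D = NIWParams(mean0=np.zeros(2), kappa0=0.01, psi=np.eye(2), df=2)


def _single_group_dag():
    return build_dag([], observed={1: True})


class TestSaltPropose:
    def test_zero_scale_is_identity(self, rng):
        x = np.array([0.2, 0.3, 0.5])
        prop, log_h = salt_propose(x, 1, 0.0, rng)
        np.testing.assert_allclose(prop, x, atol=1e-12)
        assert abs(log_h) < 1e-10

    @settings(deadline=None, max_examples=50)
    @given(
        seed=st.integers(0, 2**31 - 1),
        coord=st.integers(0, 3),
        scale=st.floats(0.01, 5.0),
    )
    def test_proposal_stays_on_simplex(self, seed, coord, scale):
        r = np.random.default_rng(seed)
        x = sample_dirichlet(r, np.full(4, 1.5))
        prop, log_h = salt_propose(x, coord, scale, r)
        assert prop.sum() == pytest.approx(1.0, abs=1e-10)
        assert (prop > 0).all()
        assert np.isfinite(log_h)

    def test_degenerate_coordinate_rejected(self, rng):
        with pytest.raises(ValueError):
            salt_propose(np.array([0.0, 1.0]), 0, 0.5, rng)

    def test_detailed_balance_on_dirichlet_target(self):
        """A short MH run with the SALT proposal keeps Dir(2, 3, 4) invariant."""
        rng = np.random.default_rng(31)
        alpha = np.array([2.0, 3.0, 4.0])

        def lt(x):
            return float(((alpha - 1) * np.log(x)).sum())

        x = np.full(3, 1 / 3)
        total = np.zeros(3)
        n = 20_000
        for _ in range(n):
            x, _, _ = salt_metropolis_sweep(x, lt, 1.0, rng)
            total += x
        assert np.abs(total / n - alpha / 9).max() < 0.01


class TestAssignments:
    def test_point_mass_component(self, rng):
        dag = _single_group_dag()
        L = 3
        w = WeightState(
            beta_root=np.array([1 - 2e-12, 1e-12, 1e-12]), nu={}, beta={}, L=L
        )
        atoms = sample_atoms(G0_2D, L, rng)
        data = GroupedDataset(x={1: rng.normal(size=(20, 2))})
        z = update_assignments(data, w, atoms, rng, dag)
        assert (z.z[1] == 0).all()

    def test_matches_hand_computed_softmax(self):
        """Empirical frequencies match log beta + log density softmax."""
        dag = _single_group_dag()
        rng = np.random.default_rng(32)
        beta = np.array([0.5, 0.2, 0.3])
        w = WeightState(beta_root=beta, nu={}, beta={}, L=3)
        means = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        covs = np.stack([np.eye(2), 2 * np.eye(2), 0.5 * np.eye(2)])
        from graphdp.gdp_prior import AtomSet

        atoms = AtomSet(means=means, covs=covs)
        x0 = np.array([0.4, 0.6])
        n = 40_000
        data = GroupedDataset(x={1: np.tile(x0, (n, 1))})
        z = update_assignments(data, w, atoms, rng, dag)
        logp = np.array(
            [
                np.log(beta[l]) + stats.multivariate_normal(means[l], covs[l]).logpdf(x0)
                for l in range(3)
            ]
        )
        p = np.exp(logp - logp.max())
        p /= p.sum()
        freqs = np.bincount(z.z[1], minlength=3) / n
        assert np.abs(freqs - p).max() < 4 * np.sqrt(p.max() * (1 - p.max()) / n)

    def test_symmetric_atoms_split_evenly(self):
        dag = _single_group_dag()
        rng = np.random.default_rng(33)
        from graphdp.gdp_prior import AtomSet

        atoms = AtomSet(means=np.zeros((2, 2)), covs=np.stack([np.eye(2)] * 2))
        w = WeightState(beta_root=np.array([0.5, 0.5]), nu={}, beta={}, L=2)
        data = GroupedDataset(x={1: rng.normal(size=(20_000, 2))})
        z = update_assignments(data, w, atoms, rng, dag)
        frac = (z.z[1] == 0).mean()
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / 20_000)


class TestAtomUpdates:
    def test_niw_posterior_single_observation(self):
        g0 = NIWParams(mean0=np.array([1.0, -1.0]), kappa0=2.0, psi=np.eye(2), df=4)
        y = np.array([[3.0, 1.0]])
        post = _niw_posterior(y, g0)
        np.testing.assert_allclose(post.mean0, (2.0 * g0.mean0 + y[0]) / 3.0)
        assert post.kappa0 == 3.0
        assert post.df == 5.0

    def test_niw_posterior_five_point_closed_form(self):
        """Posterior hyperparameters equal the sufficient-statistic formulas."""
        g0 = NIWParams(mean0=np.array([0.5, 0.5]), kappa0=1.5, psi=2 * np.eye(2), df=5)
        x = np.array([[1.0, 2.0], [0.0, -1.0], [2.0, 2.0], [-1.0, 0.5], [0.5, 0.0]])
        post = _niw_posterior(x, g0)
        n, xbar = 5, x.mean(axis=0)
        S = (x - xbar).T @ (x - xbar)
        kn = g0.kappa0 + n
        np.testing.assert_allclose(post.mean0, (g0.kappa0 * g0.mean0 + n * xbar) / kn)
        np.testing.assert_allclose(post.kappa0, kn)
        np.testing.assert_allclose(post.df, g0.df + n)
        diff = xbar - g0.mean0
        np.testing.assert_allclose(
            post.psi, g0.psi + S + g0.kappa0 * n / kn * np.outer(diff, diff)
        )

    def test_empty_component_draws_from_prior(self):
        """With no assigned data the update is distributionally the prior draw."""
        data = GroupedDataset(x={1: np.zeros((0, 2))})
        z = AssignmentState(z={1: np.empty(0, dtype=int)})
        g0 = NIWParams(mean0=np.zeros(2), kappa0=1.0, psi=np.eye(2), df=5)
        a = update_atoms(data, z, g0, 1, np.random.default_rng(77))
        b = sample_atoms(g0, 1, np.random.default_rng(77))
        np.testing.assert_allclose(a.means, b.means)
        np.testing.assert_allclose(a.covs, b.covs)


class TestNodeWeightUpdate:
    def test_zero_counts_is_prior_draw(self):
        nu = np.array([0.5, 0.3, 0.2])
        a = update_node_weights(np.zeros(3), nu, 4.0, np.random.default_rng(5))
        b = sample_dirichlet(np.random.default_rng(5), 4.0 * nu)
        np.testing.assert_allclose(a, b)

    def test_posterior_mean_formula(self):
        rng = np.random.default_rng(34)
        nu = np.array([0.6, 0.3, 0.1])
        counts = np.array([3, 10, 2])
        alpha = 5.0
        draws = np.array(
            [update_node_weights(counts, nu, alpha, rng) for _ in range(30_000)]
        )
        expected = (alpha * nu + counts) / (alpha + counts.sum())
        se = draws.std(axis=0) / np.sqrt(draws.shape[0])
        assert (np.abs(draws.mean(axis=0) - expected) < 3 * se).all()

    def test_large_counts_dominate(self):
        rng = np.random.default_rng(35)
        counts = np.array([9_000, 1_000, 0])
        w = update_node_weights(counts, np.full(3, 1 / 3), 2.0, rng)
        np.testing.assert_allclose(w, [0.9, 0.1, 0.0], atol=0.02)


class TestHiddenWeightUpdate:
    def test_two_node_chain_matches_importance_sampling(self):
        """Posterior mean of beta_root given a fixed child matches an IS oracle.

        Chain root -> a with L = 3: the root-weight conditional is
        Dir(alpha_r/L) prior times Dir(beta_a; alpha_a * beta_root).
        """
        dag = build_dag([(0, 1)], observed={0: False})
        conc = ConcentrationState(alpha0=3.0, alpha_root=3.0, alpha={1: 6.0})
        beta_a = np.array([0.6, 0.3, 0.1])
        L = 3

        # importance sampling oracle on 2*10^5 prior draws
        rng = np.random.default_rng(36)
        prior = sample_dirichlet(rng, np.full(L, conc.alpha_root / L), size=200_000)
        conc_mat = conc.alpha[1] * prior
        logw = (
            gammaln(conc_mat.sum(axis=1))
            - gammaln(conc_mat).sum(axis=1)
            + ((conc_mat - 1) * np.log(beta_a)[None, :]).sum(axis=1)
        )
        w = np.exp(logw - logw.max())
        is_mean = (prior * w[:, None]).sum(axis=0) / w.sum()

        # MH chain over the same conditional via update_hidden_weights
        weights = WeightState(
            beta_root=np.full(L, 1 / 3), nu={}, beta={1: beta_a}, L=L
        )
        rng2 = np.random.default_rng(37)
        total = np.zeros(L)
        n_keep, burn = 30_000, 2_000
        for it in range(n_keep + burn):
            update_hidden_weights(dag, weights, conc, rng2, scales={"root": 1.0})
            if it >= burn:
                total += weights.beta_root
        mh_mean = total / n_keep
        assert np.abs(mh_mean - is_mean).max() < 0.01

    def test_acceptance_rates_reasonable(self, fig_dag):
        rng = np.random.default_rng(38)
        from graphdp import sample_concentrations, sample_weight_state

        conc = sample_concentrations(fig_dag, 5.0, rng)
        weights = sample_weight_state(fig_dag, conc, 5, rng)
        accept: dict = {}
        for _ in range(200):
            update_hidden_weights(
                fig_dag, weights, conc, rng,
                scales={}, accept=accept,
            )
        for key, (na, np_) in accept.items():
            assert 0 < na < np_, f"degenerate acceptance for {key}"


class TestRunGibbs:
    def test_bookkeeping_single_draw(self):
        dag = _single_group_dag()
        rng = np.random.default_rng(39)
        data = GroupedDataset(x={1: rng.normal(size=(12, 2))})
        cfg = SamplerConfig(n_iter=6, burn_in=5, thin=1, seed=3)
        s = run_gibbs(data, dag, G0_2D, 5.0, 3, cfg)
        assert s.n_draws == 1
        assert loglik_trace(s).shape == (1,)

    def test_seed_reproducibility(self):
        dag = _single_group_dag()
        rng = np.random.default_rng(40)
        data = GroupedDataset(x={1: rng.normal(size=(30, 2))})
        cfg = SamplerConfig(n_iter=40, burn_in=20, thin=2, seed=11)
        a = run_gibbs(data, dag, G0_2D, 5.0, 4, cfg)
        b = run_gibbs(data, dag, G0_2D, 5.0, 4, cfg)
        np.testing.assert_array_equal(a.z, b.z)
        np.testing.assert_array_equal(a.beta_root, b.beta_root)
        np.testing.assert_array_equal(a.loglik, b.loglik)

    def test_simplices_stay_normalized(self, fig_dag):
        from graphdp import preset_designs, simulate_grouped_data

        data, *_ = simulate_grouped_data(preset_designs("small"))
        cfg = SamplerConfig(n_iter=30, burn_in=10, thin=2, seed=5)
        s = run_gibbs(data, fig_dag, G0_2D, 5.0, 5, cfg)
        np.testing.assert_allclose(s.beta_root.sum(axis=1), 1.0, atol=1e-10)
        for v in s.beta.values():
            np.testing.assert_allclose(v.sum(axis=1), 1.0, atol=1e-10)
        for v in s.nu.values():
            np.testing.assert_allclose(v.sum(axis=1), 1.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_blob_recovery_single_group(self, seed):
        """Two 10-sd-separated blobs are recovered exactly from any seed."""
        dag = _single_group_dag()
        rng = np.random.default_rng(100 + seed)
        x = np.vstack(
            [rng.normal(0, 1, size=(30, 2)), rng.normal(10, 1, size=(30, 2))]
        )
        truth = np.repeat([0, 1], 30)
        data = GroupedDataset(x={1: x})
        cfg = SamplerConfig(n_iter=600, burn_in=300, thin=5, seed=seed)
        s = run_gibbs(data, dag, G0_2D, 5.0, 10, cfg)
        res = dahl_estimate(s)
        assert adjusted_rand(res.labels, truth) == 1.0

    def test_fork_dag_runs_as_hdp(self):
        from graphdp import fork_dag

        dag = fork_dag(2)
        rng = np.random.default_rng(41)
        data = GroupedDataset(
            x={1: rng.normal(size=(15, 2)), 2: rng.normal(3, 1, size=(15, 2))}
        )
        cfg = SamplerConfig(n_iter=30, burn_in=10, thin=2, seed=7)
        s = run_gibbs(data, dag, G0_2D, 5.0, 4, cfg)
        assert s.n_draws == 10
        assert set(s.beta) == {1, 2}
        assert s.nu == {}

    def test_loglik_trace_matches_manual_recomputation(self):
        dag = _single_group_dag()
        rng = np.random.default_rng(42)
        x = rng.normal(size=(8, 2))
        data = GroupedDataset(x={1: x})
        cfg = SamplerConfig(n_iter=12, burn_in=8, thin=2, seed=13)
        s = run_gibbs(data, dag, G0_2D, 5.0, 3, cfg)
        d = s.n_draws - 1
        manual = 0.0
        for i in range(8):
            zi = s.z[d, i]
            manual += np.log(s.beta_root[d, zi])
            manual += stats.multivariate_normal(
                s.means[d, zi], s.covs[d, zi]
            ).logpdf(x[i])
        assert s.loglik[d] == pytest.approx(manual, rel=1e-10)

    def test_rejects_unknown_groups_and_bad_L(self):
        dag = _single_group_dag()
        data = GroupedDataset(x={2: np.zeros((3, 2))})
        with pytest.raises(ValueError):
            run_gibbs(data, dag, G0_2D, 5.0, 3, SamplerConfig(n_iter=2, burn_in=1))
        data_ok = GroupedDataset(x={1: np.zeros((3, 2))})
        with pytest.raises(ValueError):
            run_gibbs(data_ok, dag, G0_2D, 5.0, 1, SamplerConfig(n_iter=2, burn_in=1))
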