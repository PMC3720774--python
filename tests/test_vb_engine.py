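import dataclasses

import numpy as np
import pytest
from scipy import stats

import bacon
from bacon.linear_model_core import HyperPriors
from bacon.vb_engine import (ModelConfig, compute_elbo, fit, fit_no_clustering,
                             hard_memberships, init_posterior, standardize,
                             update_dynamics, update_hyperparameters,
                             update_memberships, update_precisions,
                             update_states)
from conftest import small_instance

UPDATES = [
    ("states", lambda st, d: update_states(st, d)),
    ("dynamics", lambda st, d: update_dynamics(st, d)),
    ("memberships", lambda st, d: update_memberships(st, d)),
    ("precisions", lambda st, d: update_precisions(st, d)),
    ("hyperparameters", lambda st, d: update_hyperparameters(st)),
]


class TestInit:
    def test_same_seed_bitwise_identical(self):
        data, _, _ = bacon.simulate(bacon.SimSpec(K=2, G=5, T=6, n_series=1, seed=0))
        sdata, _ = standardize(data)
        cfg = ModelConfig(K=2, seed=7)
        a = init_posterior(sdata, cfg)
        b = init_posterior(sdata, cfg)
        assert np.array_equal(a.resp, b.resp)
        for s in range(a.n_series):
            assert np.array_equal(a.x_mean[s], b.x_mean[s])
        assert np.array_equal(a.beta_mean, b.beta_mean)

    def test_k1_responsibilities_all_one(self):
        data, _, _ = bacon.simulate(bacon.SimSpec(K=1, G=4, T=5, n_series=1, seed=0))
        st = init_posterior(data, ModelConfig(K=1))
        np.testing.assert_array_equal(st.resp, np.ones((4, 1)))

    def test_identity_clamp_is_identity_pattern(self):
        data, _, _ = bacon.simulate(bacon.SimSpec(K=4, G=4, T=5, n_series=1, seed=0))
        st = init_posterior(data, ModelConfig(K=4, clamp_memberships=tuple(range(4))))
        np.testing.assert_array_equal(st.resp, np.eye(4))

    def test_more_clusters_than_genes_rejected(self):
        data, _, _ = bacon.simulate(bacon.SimSpec(K=2, G=3, T=5, n_series=1, seed=0))
        with pytest.raises(ValueError, match="exceeds"):
            init_posterior(data, ModelConfig(K=5))


class TestStateUpdate:
    def test_high_obs_precision_pulls_state_to_gene_mean(self):
        """K=1, B=d=0, diffuse state prior, huge E[tau]: the cluster state at
        each time point approaches the cross-gene mean of the observations."""
        data, _, _ = bacon.simulate(bacon.SimSpec(K=1, G=6, T=5, n_series=1, seed=1))
        sdata, _ = standardize(data)
        st = init_posterior(sdata, ModelConfig(K=1))
        st.beta_mean[:] = 0.0
        st.beta_cov[:] = 1e-12 * np.eye(2)
        st.ard_x1[:] = 1e-8
        st.tau_a[:] = 1e8
        st.tau_b[:] = 1.0  # E[tau] = 1e8
        update_states(st, sdata)
        expected = sdata.series[0].values.mean(axis=0)
        np.testing.assert_allclose(st.x_mean[0][0], expected, atol=1e-5)

    def test_zero_obs_precision_returns_to_prior(self):
        data, _, _ = bacon.simulate(bacon.SimSpec(K=1, G=4, T=4, n_series=1, seed=2))
        sdata, _ = standardize(data)
        st = init_posterior(sdata, ModelConfig(K=1))
        st.beta_mean[:] = 0.0
        st.beta_cov[:] = 1e-12 * np.eye(2)
        st.tau_a[:] = 1e-12
        st.tau_b[:] = 1.0  # E[tau] ~ 0
        update_states(st, sdata)
        np.testing.assert_allclose(st.x_mean[0][:, 0], 0.0, atol=1e-9)


class TestDynamicsUpdate:
    def test_huge_ard_prior_dominates(self):
        sdata, st, _, _ = small_instance(3, sweeps=1)
        st.ard_beta[:] = 1e10
        update_dynamics(st, sdata)
        np.testing.assert_allclose(st.beta_mean, 0.0, atol=1e-6)
        np.testing.assert_allclose(
            st.beta_cov, np.broadcast_to(1e-10 * np.eye(st.K + 1),
                                         st.beta_cov.shape), rtol=1e-3, atol=1e-16)

    @pytest.mark.parametrize("seed", range(5))
    def test_clamped_states_match_conjugate_regression(self, seed):
        """With point-mass states and identity memberships the row posteriors
        equal textbook conjugate Bayesian linear regression."""
        G = 3
        data, _, _ = bacon.simulate(
            bacon.SimSpec(K=G, G=G, T=8, n_series=2, seed=seed))
        sdata, _ = standardize(data)
        cfg = ModelConfig(K=G, clamp_memberships=tuple(range(G)), seed=seed)
        st = init_posterior(sdata, cfg)
        for s, table in enumerate(sdata.series):
            st.x_mean[s] = table.values.copy()
            st.x_cov[s][:] = 0.0
        update_dynamics(st, sdata)
        e_rho = st.e_rho()
        for j in range(G):
            Lam = np.diag(st.ard_beta[j]).astype(float)
            rhs = np.zeros(G + 1)
            for s, table in enumerate(sdata.series):
                X = table.values
                for t in range(X.shape[1] - 1):
                    w = np.append(X[:, t], 1.0)
                    Lam += e_rho[s, j] * np.outer(w, w)
                    rhs += e_rho[s, j] * w * X[j, t + 1]
            mean = np.linalg.solve(Lam, rhs)
            np.testing.assert_allclose(st.beta_mean[j], mean, atol=1e-8)
            np.testing.assert_allclose(st.beta_cov[j], np.linalg.inv(Lam), atol=1e-8)


class TestMembershipUpdate:
    def test_identical_genes_get_identical_rows(self):
        sdata, st, _, _ = small_instance(4, sweeps=1)
        # duplicate gene 0's observations into gene 1
        for table in sdata.series:
            table.values[1] = table.values[0]
        update_memberships(st, sdata)
        np.testing.assert_allclose(st.resp[0], st.resp[1], atol=1e-12)

    def test_gene_matching_cluster_mean_is_claimed(self):
        sdata, st, _, _ = small_instance(5, K=2, sweeps=1)
        st.tau_a[:] = 100.0
        st.tau_b[:] = 1.0
        # make gene 0 exactly cluster 1's trajectory, far from cluster 0's
        for s, table in enumerate(sdata.series):
            st.x_mean[s][0] = -5.0
            st.x_mean[s][1] = table.values[0]
            st.x_cov[s][:] = 1e-6 * np.eye(2)
        update_memberships(st, sdata)
        assert st.resp[0, 1] > 0.99

    def test_clamped_is_noop(self):
        G = 4
        data, _, _ = bacon.simulate(bacon.SimSpec(K=G, G=G, T=5, n_series=1, seed=0))
        st = init_posterior(data, ModelConfig(K=G, clamp_memberships=tuple(range(G))))
        before = st.resp.copy()
        update_memberships(st, data)
        np.testing.assert_array_equal(st.resp, before)


class TestPrecisionUpdate:
    def test_matches_naive_expected_residual_expansion(self):
        """Rate parameters agree with a brute-force loop implementation of
        E[(y - x)^2] = (y - m)^2 + V and the transition analogue."""
        sdata, st, _, _ = small_instance(6, K=2, G=4, T=4, n_series=1, sweeps=2)
        hyper = st.config.hyper
        # naive tau rate
        resid = 0.0
        table = sdata.series[0]
        m, V = st.x_mean[0], st.x_cov[0]
        for rep in table.all_replicates():
            for i in range(table.n_genes):
                for k in range(st.K):
                    for t in range(table.n_times):
                        resid += st.resp[i, k] * ((rep[i, t] - m[k, t]) ** 2 + V[t, k, k])
        # naive rho rates
        M2 = st.beta_second_moment()
        rho_rate = np.zeros(st.K)
        for j in range(st.K):
            for t in range(table.n_times - 1):
                w = np.append(m[:, t], 1.0)
                Eww = np.outer(w, w)
                Eww[:st.K, :st.K] += V[t]
                rho_rate[j] += ((m[j, t + 1] ** 2 + V[t + 1, j, j])
                                - 2.0 * m[j, t + 1] * (st.beta_mean[j] @ w)
                                + np.sum(Eww * M2[j]))
        update_precisions(st, sdata)
        assert st.tau_b[0] == pytest.approx(hyper.b0 + 0.5 * resid, abs=1e-10)
        np.testing.assert_allclose(st.rho_b[0], hyper.b0 + 0.5 * rho_rate, atol=1e-10)

    def test_shape_counts_observations(self):
        sdata, st, _, _ = small_instance(7, G=5, T=6, n_series=2, sweeps=1)
        update_precisions(st, sdata)
        hyper = st.config.hyper
        assert st.tau_a[0] == hyper.a0 + 0.5 * 5 * 6
        assert np.all(st.rho_a == hyper.a0 + 0.5 * 5)


class TestHyperparameterUpdate:
    def test_fixed_point_is_inverse_second_moment(self):
        sdata, st, _, _ = small_instance(8, sweeps=1)
        st.beta_mean[0, 0] = 2.0
        st.beta_cov[0] = np.eye(st.K + 1)
        update_hyperparameters(st)
        assert st.ard_beta[0, 0] == pytest.approx(1.0 / 5.0)

    def test_clipping(self):
        sdata, st, _, _ = small_instance(9, sweeps=1)
        st.beta_mean[:] = 0.0
        st.beta_cov[:] = 1e-12 * np.eye(st.K + 1)
        update_hyperparameters(st)
        assert np.all(st.ard_beta == st.config.hyper.ard_bounds[1])


class TestElboMonotonicity:
    @pytest.mark.parametrize("seed", range(10))
    def test_every_update_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        sdata, st, _, _ = small_instance(
            seed, K=int(rng.integers(1, 4)), G=int(rng.integers(3, 8)),
            T=int(rng.integers(3, 8)), n_series=2)
        elbo = compute_elbo(st, sdata)
        for _ in range(2):
            for name, upd in UPDATES:
                upd(st, sdata)
                new = compute_elbo(st, sdata)
                assert new >= elbo - 1e-8 * max(1.0, abs(elbo)), \
                    f"{name} decreased the ELBO"
                elbo = new

    def test_dynamics_hyperparameter_alternation(self):
        sdata, st, _, _ = small_instance(11, sweeps=1)
        elbo = compute_elbo(st, sdata)
        for _ in range(100):
            update_dynamics(st, sdata)
            update_hyperparameters(st)
            new = compute_elbo(st, sdata)
            assert new >= elbo - 1e-8 * max(1.0, abs(elbo))
            elbo = new


class TestElboValue:
    def test_matches_monte_carlo_estimate(self):
        """compute_elbo agrees with a Monte Carlo estimate of
        E_q[log p - log q] obtained by sampling from q (independent oracle)."""
        sdata, st, _, _ = small_instance(13, K=2, G=3, T=4, n_series=1, sweeps=3)
        hyper = st.config.hyper
        rng = np.random.default_rng(0)
        n = 4000
        table = sdata.series[0]
        Y = np.stack(table.all_replicates())
        K, T, G = st.K, table.n_times, table.n_genes
        m, V = st.x_mean[0], st.x_cov[0]
        vals = np.empty(n)
        chol_x = [np.linalg.cholesky(V[t]) for t in range(T)]
        chol_b = [np.linalg.cholesky(st.beta_cov[j]) for j in range(K)]
        for it in range(n):
            x = np.stack([m[:, t] + chol_x[t] @ rng.standard_normal(K)
                          for t in range(T)], axis=1)
            beta = np.stack([st.beta_mean[j] + chol_b[j] @ rng.standard_normal(K + 1)
                             for j in range(K)])
            z = np.array([rng.choice(K, p=st.resp[i]) for i in range(G)])
            tau = rng.gamma(st.tau_a[0], 1.0 / st.tau_b[0])
            rho = rng.gamma(st.rho_a[0], 1.0 / st.rho_b[0])
            logp = 0.0
            for r in range(Y.shape[0]):
                logp += stats.norm.logpdf(Y[r], loc=x[z], scale=tau**-0.5).sum()
            logp += stats.norm.logpdf(x[:, 0], 0.0, st.ard_x1[0] ** -0.5).sum()
            for t in range(T - 1):
                pred = beta[:, :K] @ x[:, t] + beta[:, K]
                logp += stats.norm.logpdf(x[:, t + 1], pred, rho**-0.5).sum()
            logp += stats.norm.logpdf(beta, 0.0, st.ard_beta**-0.5).sum()
            logp += stats.gamma.logpdf(tau, hyper.a0, scale=1.0 / hyper.b0)
            logp += stats.gamma.logpdf(rho, hyper.a0, scale=1.0 / hyper.b0).sum()
            logp += -G * np.log(K)
            logq = 0.0
            for t in range(T):
                logq += stats.multivariate_normal.logpdf(x[:, t], m[:, t], V[t])
            for j in range(K):
                logq += stats.multivariate_normal.logpdf(
                    beta[j], st.beta_mean[j], st.beta_cov[j])
            logq += np.log(st.resp[np.arange(G), z]).sum()
            logq += stats.gamma.logpdf(tau, st.tau_a[0], scale=1.0 / st.tau_b[0])
            logq += stats.gamma.logpdf(rho, st.rho_a[0], scale=1.0 / st.rho_b[0]).sum()
            vals[it] = logp - logq
        se = vals.std(ddof=1) / np.sqrt(n)
        assert compute_elbo(st, sdata) == pytest.approx(vals.mean(), abs=5 * se)


class TestFit:
    def test_deterministic_given_seed(self):
        data, _, _ = bacon.simulate(bacon.SimSpec(K=2, G=6, T=8, n_series=2, seed=3))
        cfg = ModelConfig(K=2, max_sweeps=30, seed=9)
        a = fit(data, cfg)
        b = fit(data, cfg)
        assert a.elbo_trace == b.elbo_trace
        np.testing.assert_array_equal(a.resp, b.resp)

    def test_zero_sweeps_returns_initialization(self):
        data, _, _ = bacon.simulate(bacon.SimSpec(K=2, G=5, T=6, n_series=1, seed=4))
        cfg = ModelConfig(K=2, max_sweeps=0, seed=1)
        st = fit(data, cfg)
        sdata, _ = standardize(data)
        ref = init_posterior(sdata, cfg)
        assert st.elbo_trace == []
        np.testing.assert_array_equal(st.resp, ref.resp)
        np.testing.assert_array_equal(st.beta_mean, ref.beta_mean)

    def test_trace_non_decreasing_and_converges(self):
        data, _, _ = bacon.simulate(bacon.SimSpec(K=3, G=9, T=15, n_series=2, seed=5))
        st = fit(data, ModelConfig(K=3, max_sweeps=500, rel_tol=1e-6, seed=2))
        tr = np.array(st.elbo_trace)
        assert st.converged
        assert np.all(np.diff(tr) >= -1e-8 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_responsibilities_normalized_after_fit(self):
        data, _, _ = bacon.simulate(bacon.SimSpec(K=3, G=8, T=10, n_series=2, seed=6))
        st = fit(data, ModelConfig(K=3, max_sweeps=60, seed=0))
        np.testing.assert_allclose(st.resp.sum(axis=1), 1.0, atol=1e-12)

    def test_permutation_equivariance(self):
        """Relabeling clusters in the initialization permutes the fitted
        factors and leaves the ELBO and gene-level edge scores unchanged."""
        data, _, _ = bacon.simulate(bacon.SimSpec(K=3, G=9, T=12, n_series=2, seed=7))
        sdata, _ = standardize(data)
        cfg = ModelConfig(K=3, max_sweeps=80, seed=3)
        base = init_posterior(sdata, cfg)
        perm = np.array([2, 0, 1])
        permuted = base.copy()
        permuted.resp = base.resp[:, perm]
        permuted.ard_x1 = base.ard_x1[:, perm]
        for s in range(base.n_series):
            permuted.x_mean[s] = base.x_mean[s][perm]
            permuted.x_cov[s] = base.x_cov[s][:, perm][:, :, perm]
        a = fit(sdata, cfg, standardize_input=False, init_state=base)
        b = fit(sdata, cfg, standardize_input=False, init_state=permuted)
        assert a.elbo_trace[-1] == pytest.approx(b.elbo_trace[-1], rel=1e-8)
        np.testing.assert_allclose(a.resp[:, perm], b.resp, atol=1e-6)
        sa = bacon.cluster_scores(a)
        sb = bacon.cluster_scores(b)
        np.testing.assert_allclose(sa[np.ix_(perm, perm)], sb, atol=1e-5)

    def test_no_clustering_is_identity_clamped_k_equals_g(self):
        data, _, _ = bacon.simulate(bacon.SimSpec(K=4, G=4, T=10, n_series=2, seed=8))
        st = fit_no_clustering(data, ModelConfig(K=4, max_sweeps=50, seed=1))
        assert st.K == data.n_genes
        np.testing.assert_array_equal(st.resp, np.eye(4))
        np.testing.assert_array_equal(hard_memberships(st), np.arange(4))
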