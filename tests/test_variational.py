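"""Variational posterior updates, expected parameters and the training loop."""

import numpy as np
import pytest

from sdhmm import (
    FitConfig,
    HMMParams,
    PriorConfig,
    VariationalPosterior,
    e_step,
    expected_params,
    fit,
    m_step_emissions,
    m_step_structural,
    prune_components,
)
from sdhmm.hmm import Responsibilities
from sdhmm.variational import ExpectedParams, load_checkpoint, save_checkpoint, to_hmm_params
from sdhmm.synthetic import SimulationSpec, simulate
from sdhmm.evaluation import evaluate


def make_posterior(K=1, M=1, D=2, w=1.0, u=6.0, v=2.0, h=2.0):
    return VariationalPosterior(
        w_pi=np.full(K, w),
        w_B=np.full((K, K), w),
        w_C=np.full((K, M), w),
        u_star=np.full((K, M, D), u),
        v_star=np.full((K, M, D), v),
        h_star=np.full((K, M, D), h),
    )


class TestExpectedParams:
    def test_digamma_identity_for_symmetric_weights(self):
        # psi(2) - psi(1) = 1 exactly, so each tilde entry is e^{-1}
        exp = expected_params(make_posterior(K=2, M=1))
        np.testing.assert_allclose(exp.pi_tilde, np.exp(-1.0), atol=1e-12)
        np.testing.assert_allclose(exp.B_tilde, np.exp(-1.0), atol=1e-12)

    def test_gamma_mean_and_dirichlet_mean(self):
        exp = expected_params(make_posterior(u=6.0, v=2.0, h=2.0))
        np.testing.assert_allclose(exp.alpha_bar, 3.0)
        np.testing.assert_allclose(exp.beta_bar, 0.5)

    def test_tilde_rows_subnormalized(self):
        rng = np.random.default_rng(0)
        post = make_posterior(K=3, M=2)
        post.w_B = rng.uniform(0.5, 5.0, (3, 3))
        post.w_C = rng.uniform(0.5, 5.0, (3, 2))
        exp = expected_params(post)
        assert np.all(exp.B_tilde.sum(axis=1) <= 1.0 + 1e-12)
        assert np.all(exp.C_tilde.sum(axis=1) <= 1.0 + 1e-12)
        assert np.all(exp.B_tilde > 0)

    def test_nonpositive_posterior_rejected(self):
        post = make_posterior()
        post.u_star = np.zeros_like(post.u_star)
        with pytest.raises(ValueError):
            expected_params(post)


class TestStructuralUpdates:
    def test_empty_responsibilities_return_prior(self):
        prior = PriorConfig.default(2, 2, 3)
        resp = Responsibilities(
            gamma_sc=np.zeros((0, 2, 2)),
            xi=np.zeros((0, 2, 2)),
            gamma_init=np.zeros(2),
            loglik=0.0,
        )
        w_pi, w_B, w_C = m_step_structural(resp, prior)
        np.testing.assert_array_equal(w_pi, prior.phi_pi)
        np.testing.assert_array_equal(w_B, prior.phi_B)
        np.testing.assert_array_equal(w_C, prior.phi_C)

    def test_hand_accumulated_two_step_counts(self):
        prior = PriorConfig.default(2, 1, 2)
        gamma_sc = np.array([[[0.9], [0.1]], [[0.2], [0.8]]])  # (T=2, K=2, M=1)
        xi = np.array([[[0.15, 0.75], [0.05, 0.05]]])  # (1, 2, 2)
        resp = Responsibilities(gamma_sc=gamma_sc, xi=xi, gamma_init=np.array([0.9, 0.1]), loglik=0.0)
        w_pi, w_B, w_C = m_step_structural(resp, prior)
        np.testing.assert_allclose(w_pi, [1.9, 1.1])
        np.testing.assert_allclose(w_B, [[1.15, 1.75], [1.05, 1.05]])
        np.testing.assert_allclose(w_C, [[2.1], [1.9]])

    def test_row_sums_count_expected_visits(self):
        rng = np.random.default_rng(2)
        prior = PriorConfig.default(3, 1, 2)
        T = 10
        xi = rng.dirichlet(np.ones(9), size=T - 1).reshape(T - 1, 3, 3)
        gamma_sc = rng.dirichlet(np.ones(3), size=T).reshape(T, 3, 1)
        resp = Responsibilities(gamma_sc=gamma_sc, xi=xi, gamma_init=gamma_sc[0, :, 0], loglik=0.0)
        _, w_B, _ = m_step_structural(resp, prior)
        np.testing.assert_allclose(
            (w_B - prior.phi_B).sum(axis=1), xi.sum(axis=(0, 2)), atol=1e-12
        )


class TestEmissionUpdates:
    def test_zero_responsibilities_leave_posterior_at_prior(self):
        prior = PriorConfig.default(1, 2, 2)
        exp = expected_params(make_posterior(K=1, M=2))
        X = np.array([[0.4, 0.6], [0.3, 0.7], [0.5, 0.5]])
        resp = Responsibilities(
            gamma_sc=np.zeros((3, 1, 2)), xi=np.zeros((2, 1, 1)),
            gamma_init=np.zeros(1), loglik=0.0,
        )
        u, v, h, inter = m_step_emissions(X, resp, exp, prior)
        np.testing.assert_array_equal(u, prior.u)
        np.testing.assert_array_equal(v, prior.v)
        np.testing.assert_array_equal(h, prior.h)
        np.testing.assert_array_equal(inter.eta, 0.0)
        np.testing.assert_array_equal(inter.tau, 0.0)

    def test_theta_hand_value_single_observation(self):
        # uniform scale cancels: theta_d = ln x_d exactly
        prior = PriorConfig.default(1, 1, 2)
        exp = ExpectedParams(
            pi_tilde=np.array([1.0]), B_tilde=np.array([[1.0]]), C_tilde=np.array([[1.0]]),
            alpha_bar=np.array([[[2.0, 2.0]]]), ln_alpha=np.log(np.array([[[2.0, 2.0]]])),
            beta_bar=np.array([[[0.5, 0.5]]]),
        )
        X = np.array([[0.3, 0.7]])
        resp = Responsibilities(
            gamma_sc=np.ones((1, 1, 1)), xi=np.zeros((0, 1, 1)),
            gamma_init=np.ones(1), loglik=0.0,
        )
        _, _, _, inter = m_step_emissions(X, resp, exp, prior)
        np.testing.assert_allclose(inter.theta[0, 0], np.log([0.3, 0.7]), atol=1e-9)

    def test_theta_matches_direct_summation_on_toy(self):
        rng = np.random.default_rng(8)
        prior = PriorConfig.default(2, 1, 3)
        abar = rng.uniform(0.5, 4.0, (2, 1, 3))
        bbar = rng.dirichlet(np.ones(3), (2, 1))
        exp = ExpectedParams(
            pi_tilde=np.full(2, 0.5), B_tilde=np.full((2, 2), 0.5),
            C_tilde=np.ones((2, 1)), alpha_bar=abar,
            ln_alpha=np.log(abar), beta_bar=bbar,
        )
        X = rng.dirichlet(np.ones(3), size=3)
        Z = rng.dirichlet(np.ones(2), size=3).reshape(3, 2, 1)
        resp = Responsibilities(gamma_sc=Z, xi=np.zeros((2, 2, 2)), gamma_init=Z[0, :, 0], loglik=0.0)
        _, _, _, inter = m_step_emissions(X, resp, exp, prior)
        direct = np.zeros((2, 1, 3))
        for i in range(2):
            for t in range(3):
                sbx = float(bbar[i, 0] @ X[t])
                direct[i, 0] += Z[t, i, 0] * (np.log(bbar[i, 0]) + np.log(X[t]) - np.log(sbx))
        np.testing.assert_allclose(inter.theta, direct, atol=1e-9)

    def test_v_update_keeps_rate_positive(self):
        # theta <= 0 entrywise, so v* = v - theta >= v
        rng = np.random.default_rng(4)
        prior = PriorConfig.default(1, 1, 3)
        exp = expected_params(make_posterior(K=1, M=1, D=3))
        X = rng.dirichlet(np.ones(3), size=20)
        resp = Responsibilities(
            gamma_sc=np.ones((20, 1, 1)), xi=np.ones((19, 1, 1)),
            gamma_init=np.ones(1), loglik=0.0,
        )
        _, v, _, inter = m_step_emissions(X, resp, exp, prior)
        assert np.all(inter.theta <= 0)
        assert np.all(v >= prior.v)

    def test_scale_pseudocounts_carry_component_mass(self):
        rng = np.random.default_rng(6)
        prior = PriorConfig.default(1, 1, 3)
        exp = expected_params(make_posterior(K=1, M=1, D=3))
        X = rng.dirichlet([2.0, 3.0, 4.0], size=50)
        resp = Responsibilities(
            gamma_sc=np.full((50, 1, 1), 0.5), xi=np.ones((49, 1, 1)),
            gamma_init=np.ones(1), loglik=0.0,
        )
        _, _, h, inter = m_step_emissions(X, resp, exp, prior)
        assert inter.tau.sum() == pytest.approx(25.0, rel=1e-9)
        assert np.all(h > 0)


class TestEStep:
    def test_symmetric_posterior_gives_uniform_responsibilities(self):
        exp = expected_params(make_posterior(K=2, M=2, D=2))
        X = np.tile([0.5, 0.5], (6, 1))
        resp = e_step(X, exp)
        np.testing.assert_allclose(resp.gamma_sc, 0.25, atol=1e-12)

    def test_separated_emissions_concentrate_responsibilities(self):
        params = HMMParams(
            pi=np.array([0.5, 0.5]),
            B=np.array([[0.9, 0.1], [0.1, 0.9]]),
            C=np.ones((2, 1)),
            alpha=np.array([[[50.0, 5.0]], [[5.0, 50.0]]]),
            beta=np.full((2, 1, 2), 0.5),
        )
        states, seqs = simulate(SimulationSpec(params=params, T=400, seed=0))
        exp = ExpectedParams(
            pi_tilde=params.pi, B_tilde=params.B, C_tilde=params.C,
            alpha_bar=params.alpha, ln_alpha=np.log(params.alpha), beta_bar=params.beta,
        )
        resp = e_step(seqs[0], exp)
        top = resp.gamma_state.max(axis=1)
        assert np.median(top) > 0.99
        np.testing.assert_allclose(resp.gamma_sc.sum(axis=(1, 2)), 1.0, atol=1e-9)


class TestFit:
    def test_same_seed_reproduces_trace_exactly(self, rng):
        X = rng.dirichlet([2.0, 1.0, 3.0], size=150)
        cfg = FitConfig(K=2, M=1, seed=11, max_iter=25)
        r1 = fit(X, cfg)
        r2 = fit(X, cfg)
        assert r1.trace == r2.trace
        np.testing.assert_array_equal(r1.posterior.u_star, r2.posterior.u_star)

    def test_single_state_monitor_converges(self, rng):
        X = rng.dirichlet([3.0, 2.0], size=300)
        res = fit(X, FitConfig(K=1, M=1, seed=0))
        assert len(res.trace) < 200  # stopped by tolerance, not the cap
        diffs = np.diff(res.trace)
        assert (diffs >= -1e-6 * np.abs(np.array(res.trace[:-1]))).mean() >= 0.95

    def test_posterior_positivity_throughout(self, rng):
        X = rng.dirichlet([2.0, 2.0, 2.0], size=200)
        res = fit(X, FitConfig(K=2, M=2, seed=3, max_iter=30))
        for arr in (res.posterior.w_pi, res.posterior.w_B, res.posterior.w_C,
                    res.posterior.u_star, res.posterior.v_star, res.posterior.h_star):
            assert np.all(arr > 0)

    def test_too_many_components_rejected(self, rng):
        X = rng.dirichlet(np.ones(2), size=5)
        with pytest.raises(ValueError, match="exceeds"):
            fit(X, FitConfig(K=3, M=2, seed=0))

    def test_multiple_sequences_accumulate(self, rng):
        seqs = [rng.dirichlet([2.0, 5.0], size=80) for _ in range(3)]
        res = fit(seqs, FitConfig(K=1, M=1, seed=0, max_iter=40))
        assert np.isfinite(res.final_loglik)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        X = rng.dirichlet([2.0, 1.0], size=100)
        res = fit(X, FitConfig(K=2, M=1, seed=5, max_iter=15))
        path = tmp_path / "ckpt.json"
        save_checkpoint(path, res)
        back = load_checkpoint(path)
        np.testing.assert_allclose(back.posterior.u_star, res.posterior.u_star)
        assert back.trace == res.trace
        assert back.config == res.config

    def test_dirichlet_restricted_model_matches_on_equal_scale_data(self):
        params = HMMParams(
            pi=np.array([0.5, 0.5]),
            B=np.array([[0.93, 0.07], [0.07, 0.93]]),
            C=np.ones((2, 1)),
            alpha=np.array([[[1.2, 0.7, 0.5]], [[0.5, 0.7, 1.2]]]),
            beta=np.full((2, 1, 3), 1 / 3),
        )
        states, seqs = simulate(SimulationSpec(params=params, T=1500, seed=2))
        acc = {}
        for fix in (False, True):
            res = fit(seqs[0], FitConfig(K=2, M=1, seed=2, fix_beta_uniform=fix))
            dec = res.decode(seqs[0])
            acc[fix] = evaluate(states[0], dec)["accuracy"]
        assert abs(acc[True] - acc[False]) <= 0.02


class TestPrune:
    def _exp(self, C_tilde):
        K, M = C_tilde.shape
        return ExpectedParams(
            pi_tilde=np.full(K, 1 / K), B_tilde=np.full((K, K), 1 / K), C_tilde=C_tilde,
            alpha_bar=np.ones((K, M, 2)), ln_alpha=np.zeros((K, M, 2)),
            beta_bar=np.full((K, M, 2), 0.5),
        )

    def test_zero_threshold_keeps_everything(self):
        mask, C = prune_components(self._exp(np.array([[0.6, 0.3], [0.2, 0.7]])), 0.0)
        assert mask.all()
        np.testing.assert_allclose(C.sum(axis=1), 1.0)

    def test_weak_component_flagged_and_rows_renormalized(self):
        mask, C = prune_components(self._exp(np.array([[0.98, 0.01], [0.5, 0.48]])), 0.05)
        assert not mask[0, 1] and mask.sum() == 3
        np.testing.assert_allclose(C.sum(axis=1), 1.0)
        assert C[0, 1] == 0.0

    def test_all_pruned_state_is_an_error(self):
        with pytest.raises(ValueError, match="state 0"):
            prune_components(self._exp(np.array([[0.5, 0.5], [0.9, 0.1]])), 0.8)

    def test_overspecified_fit_keeps_valid_weights(self, rng):
        # an M=3 fit of two-cluster data yields a proper mixing row whatever
        # configuration (starved spare or split cluster) the optimum takes
        X = np.vstack([
            rng.dirichlet([15.0, 2.0, 2.0], size=300),
            rng.dirichlet([2.0, 2.0, 15.0], size=300),
        ])
        res = fit(X, FitConfig(K=1, M=3, seed=0, max_iter=60))
        w = res.expected.C_tilde / res.expected.C_tilde.sum(axis=1, keepdims=True)
        assert w.shape == (1, 3) and np.all(w > 0)
        mask, C = prune_components(res.expected, 0.02)
        np.testing.assert_allclose(C.sum(axis=1), 1.0)
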