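"""CTCRW transition moments, Kalman likelihood, smoother and simulator."""

import numpy as np
import pytest

import ctcrw
from ctcrw.kalman import MovementParams


def random_params(rng, n, beta_range=(0.02, 2.0), delta_range=(0.2, 8.0)):
    return MovementParams(sigma=rng.uniform(0.3, 3.0, n),
                          beta=rng.uniform(*beta_range, n),
                          delta=rng.uniform(*delta_range, n))


class TestTransitionMoments:
    def test_zero_interval_limit(self):
        T, Q = ctcrw.transition_moments(0.5, 1.0, 1e-10)
        assert np.abs(T - np.eye(2)).max() < 1e-9
        assert np.abs(Q).max() < 1e-9

    def test_stationary_limit(self):
        beta, sigma = 0.8, 1.3
        T, Q = ctcrw.transition_moments(beta, sigma, 500.0)
        assert T[1, 1] < 1e-12                       # autocorrelation gone
        assert Q[1, 1] == pytest.approx(sigma ** 2 / (2 * beta))

    def test_series_branch_is_continuous(self):
        # crossing the series/exact switch via beta at fixed delta: the
        # moments barely depend on beta there, so any jump is a branch bug
        sigma, delta = 1.2, 1.0
        lo = ctcrw.transition_moments(0.99e-4, sigma, delta)
        hi = ctcrw.transition_moments(1.01e-4, sigma, delta)
        for a, b in zip(lo, hi):
            np.testing.assert_allclose(a, b, rtol=1e-4, atol=1e-18)

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            ctcrw.transition_moments(-1.0, 1.0, 1.0)

    def test_euler_maruyama_oracle(self):
        # simulate the OU velocity / integrated position pair with a fine
        # Euler–Maruyama scheme and compare empirical second moments
        beta, sigma, delta = 1.3, 0.8, 0.5
        n_rep, dt = 30_000, 2e-4
        n_steps = int(round(delta / dt))
        rng = np.random.default_rng(20)
        v = np.full(n_rep, 0.7)   # deterministic start isolates the noise
        x = np.zeros(n_rep)
        sq = sigma * np.sqrt(dt)
        for _ in range(n_steps):
            x = x + v * dt
            v = v + (-beta * v * dt) + sq * rng.standard_normal(n_rep)
        T, Q = ctcrw.transition_moments(beta, sigma, delta)
        # means
        assert v.mean() == pytest.approx(T[1, 1] * 0.7, abs=3 * v.std()
                                         / np.sqrt(n_rep))
        assert x.mean() == pytest.approx(T[0, 1] * 0.7, abs=3 * x.std()
                                         / np.sqrt(n_rep))
        # variances / covariance (MC SE of a variance ~ var * sqrt(2/n))
        assert v.var() == pytest.approx(Q[1, 1],
                                        abs=3 * Q[1, 1] * np.sqrt(2 / n_rep))
        assert x.var() == pytest.approx(Q[0, 0],
                                        abs=3 * Q[0, 0] * np.sqrt(2 / n_rep))
        cov = np.cov(x, v)[0, 1]
        cov_se = np.sqrt((Q[0, 0] * Q[1, 1] + Q[0, 1] ** 2) / n_rep)
        assert cov == pytest.approx(Q[0, 1], abs=3 * cov_se)


def simulated_track(rng, n, **kw):
    params = random_params(rng, n - 1, **kw)
    times = np.concatenate([[0.0], np.cumsum(params.delta)])
    sd = rng.uniform(0.05, 1.5, (n, 2))
    states, obs = ctcrw.simulate_states(times, params, sd,
                                        seed=int(rng.integers(2 ** 31)),
                                        v0=(1.0, -1.0))
    return params, sd, states, obs


class TestKalmanLoglik:
    @pytest.mark.parametrize("n", [2, 5, 12])
    def test_matches_dense_joint_gaussian(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            params, sd, _, obs = simulated_track(rng, n)
            ll_k = ctcrw.kalman_loglik(obs, sd, params)
            ll_d = ctcrw.dense_loglik(obs, sd, params)
            assert ll_k == pytest.approx(ll_d, abs=1e-8)

    def test_matches_oracle_in_stiff_regimes(self):
        rng = np.random.default_rng(99)
        # near-degenerate small and large beta*delta
        for beta_range, delta_range in [((1e-6, 1e-4), (0.1, 1.0)),
                                        ((5.0, 30.0), (2.0, 10.0))]:
            params, sd, _, obs = simulated_track(
                rng, 8, beta_range=beta_range, delta_range=delta_range)
            assert ctcrw.kalman_loglik(obs, sd, params) == pytest.approx(
                ctcrw.dense_loglik(obs, sd, params), abs=1e-8)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        params, sd, _, obs = simulated_track(rng, 20)
        a = ctcrw.kalman_loglik(obs, sd, params)
        b = ctcrw.kalman_loglik(obs + 100.0, sd, params)
        assert abs(a - b) < 1e-6

    def test_doubling_observation_sds_lowers_loglik(self):
        rng = np.random.default_rng(4)
        params, sd, _, obs = simulated_track(rng, 80)
        assert ctcrw.kalman_loglik(obs, sd, params) \
            > ctcrw.kalman_loglik(obs, 2 * sd, params)

    def test_input_validation(self):
        rng = np.random.default_rng(5)
        params, sd, _, obs = simulated_track(rng, 5)
        with pytest.raises(ValueError, match="n_fixes"):
            ctcrw.kalman_loglik(obs[:4], sd[:4], params)
        obs_bad = obs.copy()
        obs_bad[2, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ctcrw.kalman_loglik(obs_bad, sd, params)

    def test_p_is_three_over_beta(self):
        p = MovementParams(sigma=[1.0, 1.0], beta=[0.5, 3.0], delta=[1.0, 1.0])
        np.testing.assert_allclose(p.p, [6.0, 1.0])


class TestSmoother:
    def test_zero_error_pins_positions_to_observations(self):
        rng = np.random.default_rng(6)
        params, _, _, obs = simulated_track(rng, 30)
        sd = np.full((30, 2), 1e-8)
        out = ctcrw.smooth_states(obs, sd, params)
        np.testing.assert_allclose(out["mean"][:, 0], obs[:, 0], atol=1e-5)
        np.testing.assert_allclose(out["mean"][:, 2], obs[:, 1], atol=1e-5)

    def test_smoothed_variance_below_filtered(self):
        rng = np.random.default_rng(7)
        params, sd, _, obs = simulated_track(rng, 40)
        out = ctcrw.smooth_states(obs, sd, params)
        for ax in range(2):
            assert np.all(out["cov"][ax, :, 0, 0]
                          <= out["filtered_var"][ax, :, 0] + 1e-9)
            assert np.all(out["cov"][ax, :, 1, 1]
                          <= out["filtered_var"][ax, :, 1] + 1e-9)

    def test_covariances_are_symmetric_psd(self):
        rng = np.random.default_rng(8)
        params, sd, _, obs = simulated_track(rng, 25)
        out = ctcrw.smooth_states(obs, sd, params)
        for ax in range(2):
            for C in out["cov"][ax]:
                assert np.allclose(C, C.T)
                assert np.linalg.eigvalsh(C).min() >= -1e-10

    def test_smoothing_beats_raw_observations(self):
        rng = np.random.default_rng(9)
        errs_obs, errs_sm = [], []
        for _ in range(10):
            params, sd, states, obs = simulated_track(rng, 120)
            out = ctcrw.smooth_states(obs, sd, params)
            truth = states[:, [0, 2]]
            errs_obs.append(np.sqrt(np.mean((obs - truth) ** 2)))
            sm = out["mean"][:, [0, 2]]
            errs_sm.append(np.sqrt(np.mean((sm - truth) ** 2)))
        assert np.mean(errs_sm) < np.mean(errs_obs)


class TestSimulator:
    def test_seed_repeatability(self):
        rng = np.random.default_rng(10)
        params = random_params(rng, 10)
        times = np.concatenate([[0.0], np.cumsum(params.delta)])
        sd = np.full(11, 0.3)
        s1, o1 = ctcrw.simulate_states(times, params, sd, seed=123)
        s2, o2 = ctcrw.simulate_states(times, params, sd, seed=123)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(o1, o2)

    def test_velocity_autocorrelation(self):
        beta, sigma, delta = 0.4, 1.0, 1.5
        n = 4000
        params = MovementParams(sigma=np.full(n - 1, sigma),
                                beta=np.full(n - 1, beta),
                                delta=np.full(n - 1, delta))
        times = np.arange(n) * delta
        states, _ = ctcrw.simulate_states(times, params, np.full(n, 0.1),
                                          seed=11)
        v = states[:, 1]
        rho = np.corrcoef(v[:-1], v[1:])[0, 1]
        assert rho == pytest.approx(np.exp(-beta * delta), abs=0.05)

    def test_likelihood_peaks_near_truth(self):
        # average loglik at the generating parameters exceeds the average
        # at sigma inflated by 20%
        rng = np.random.default_rng(12)
        diffs = []
        for _ in range(60):
            params, sd, _, obs = simulated_track(rng, 40)
            wrong = MovementParams(sigma=1.2 * params.sigma, beta=params.beta,
                                   delta=params.delta)
            diffs.append(ctcrw.kalman_loglik(obs, sd, params)
                         - ctcrw.kalman_loglik(obs, sd, wrong))
        assert np.mean(diffs) > 0
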