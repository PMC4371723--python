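"""Higher-moment ensemble particle filter against closed-form oracles."""

import numpy as np
import pytest

import oracles
from conftest import make_quadratic_params
from grnrestore import (CTMParameters, Ensemble, NetworkStructure, simulate)
from grnrestore.hmenpf import (enkf_update, filter_series, merge, pf_update,
                               predict, smooth, summarize, _sym_sqrt)


def gaussian_ensemble(rng, mean, cov, N):
    L = np.linalg.cholesky(cov)
    return mean + rng.standard_normal((N, len(mean))) @ L.T


class TestPredict:
    def test_zero_noise_identity_dynamics_unchanged(self):
        s = NetworkStructure(p=2)
        params = CTMParameters.zeros(s, q=0.0)
        ens = Ensemble(np.array([[1.0, 2.0], [3.0, -1.0]]), 1, "filtered")
        out = predict(ens, params, s, None, np.random.default_rng(0))
        np.testing.assert_array_equal(out.particles, ens.particles)
        assert out.time_index == 2 and out.N == 2

    def test_matches_kalman_prediction_on_linear_model(
            self, chain3, linear_params_chain3):
        N = 40_000
        rng = np.random.default_rng(14)
        params = linear_params_chain3
        mean0 = params.mu0
        cov0 = np.diag(params.sigma0_diag)
        ens = Ensemble(gaussian_ensemble(rng, mean0, cov0, N), 1, "filtered")
        out = predict(ens, params, chain3, None, rng)
        A = oracles.full_linear_matrix(params)
        exp_mean = A @ mean0 + params.u
        exp_cov = A @ cov0 @ A.T + np.diag(params.q_diag)
        se = np.sqrt(np.diag(exp_cov) / N)
        assert np.all(np.abs(out.particles.mean(axis=0) - exp_mean) < 3 * se)
        cov_err = np.abs(np.cov(out.particles, rowvar=False, ddof=0) - exp_cov)
        assert np.all(cov_err < 5 * np.max(exp_cov) / np.sqrt(N) * 3)

    def test_bit_identical_given_seed(self, chain3, linear_params_chain3):
        ens = Ensemble(np.ones((10, 3)), 1, "filtered")
        a = predict(ens, linear_params_chain3, chain3, None,
                    np.random.default_rng(9))
        b = predict(ens, linear_params_chain3, chain3, None,
                    np.random.default_rng(9))
        np.testing.assert_array_equal(a.particles, b.particles)


class TestPFUpdate:
    def test_equal_particles_unchanged(self):
        ens = Ensemble(np.full((50, 2), 1.3), 4, "predicted")
        out, summary = pf_update(ens, np.array([[0.0, 0.0]]), np.ones(2),
                                 np.random.default_rng(0))
        np.testing.assert_array_equal(out.particles, ens.particles)
        assert out.N == 50

    def test_two_particle_weights_match_density_ratio(self):
        """Particles {0, 1}, y=0, r=1: weights (0.6225, 0.3775)."""
        ens = Ensemble(np.array([[0.0], [1.0]]), 1, "predicted")
        counts = np.zeros(2)
        n_trials = 4000
        rng = np.random.default_rng(8)
        for _ in range(n_trials):
            out, _ = pf_update(ens, np.array([[0.0]]), np.ones(1), rng)
            counts += np.bincount((out.particles[:, 0] > 0.5).astype(int),
                                  minlength=2)
        frac0 = counts[0] / counts.sum()
        expect = 1.0 / (1.0 + np.exp(-0.5))  # 0.6225
        se = np.sqrt(expect * (1 - expect) / (2 * n_trials))
        assert abs(frac0 - expect) < 3 * se

    def test_standardized_ensemble_is_white(self):
        rng = np.random.default_rng(1)
        particles = rng.gamma(2.0, size=(4000, 3)) @ np.diag([1.0, 2.0, 0.5])
        summary = summarize(particles)
        z = (particles - summary.mean) @ _sym_sqrt(summary.cov, inverse=True)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(np.cov(z, rowvar=False, ddof=0), np.eye(3),
                                   atol=1e-8)

    def test_replicates_sharpen_the_weights(self):
        """More replicates concentrate posterior mass on the nearer particle."""
        ens = Ensemble(np.array([[0.0], [1.0]]), 1, "predicted")
        rng = np.random.default_rng(3)
        fracs = []
        for reps in (1, 4):
            counts = 0
            y = np.zeros((reps, 1))
            for _ in range(2000):
                out, _ = pf_update(ens, y, np.ones(1), rng)
                counts += np.sum(out.particles[:, 0] < 0.5)
            fracs.append(counts / (2000 * 2))
        assert fracs[1] > fracs[0]


class TestEnKFUpdate:
    def test_gain_halves_distance_when_variances_equal(self):
        """Scalar V = R: K -> 1/2, so the mean moves halfway to y."""
        rng = np.random.default_rng(5)
        N = 100_000
        ens = Ensemble(rng.standard_normal((N, 1)), 1, "predicted")
        y = np.array([[2.0]])
        out, summary = enkf_update(ens, y, np.ones(1), rng)
        se = 1.0 / np.sqrt(N)
        assert abs(summary.mean[0] - 1.0) < 5 * se

    def test_tiny_r_collapses_to_observation(self):
        rng = np.random.default_rng(6)
        ens = Ensemble(rng.standard_normal((2000, 2)) + 5.0, 1, "predicted")
        y = np.array([[0.3, -0.7]])
        out, _ = enkf_update(ens, y, np.full(2, 1e-10), rng)
        np.testing.assert_allclose(out.particles.mean(axis=0), y[0], atol=1e-3)

    def test_matches_kalman_update_on_gaussian_ensemble(self):
        rng = np.random.default_rng(7)
        N = 60_000
        mean = np.array([1.0, -1.0])
        cov = np.array([[1.0, 0.4], [0.4, 2.0]])
        r = np.array([0.5, 0.8])
        ens = Ensemble(gaussian_ensemble(rng, mean, cov, N), 1, "predicted")
        y = np.array([[0.0, 0.5]])
        out, summary = enkf_update(ens, y, r, rng)
        K = cov @ np.linalg.inv(cov + np.diag(r))
        exp_mean = mean + K @ (y[0] - mean)
        exp_cov = (np.eye(2) - K) @ cov
        se = np.sqrt(np.diag(exp_cov) / N)
        assert np.all(np.abs(summary.mean - exp_mean) < 4 * se)
        cov_se = np.max(exp_cov) * np.sqrt(2.0 / N)
        assert np.all(np.abs(summary.cov - exp_cov) < 4 * cov_se)


class TestMerge:
    def test_identity_when_summaries_identical_gaussian(self):
        rng = np.random.default_rng(2)
        particles = gaussian_ensemble(rng, np.zeros(2),
                                      np.array([[1.0, 0.3], [0.3, 0.8]]), 3000)
        ens = Ensemble(particles, 3, "filtered")
        summary = summarize(particles)
        summary.m3[:] = 0.0  # exact Gaussian targets: transforms reduce to identity
        summary.m4[:] = 3.0
        out = merge(summary, ens, summary)
        np.testing.assert_allclose(out.particles, particles, atol=1e-8)

    def test_first_two_moments_equal_pf_summary(self):
        rng = np.random.default_rng(3)
        enkf_particles = rng.standard_normal((4000, 2))
        pf_particles = rng.gamma(2.0, size=(4000, 2)) - 2.0
        pf_sum = summarize(pf_particles)
        enkf_ens = Ensemble(enkf_particles, 2, "filtered")
        out = merge(pf_sum, enkf_ens, summarize(enkf_particles))
        out_sum = summarize(out.particles)
        np.testing.assert_allclose(out_sum.mean, pf_sum.mean, atol=1e-6)
        np.testing.assert_allclose(out_sum.cov, pf_sum.cov, atol=1e-6)

    def test_skewed_pf_target_recovered(self):
        N = 20_000
        rng = np.random.default_rng(4)
        enkf_particles = rng.standard_normal((N, 1))
        pf_particles = rng.gamma(2.0, size=(N, 1))  # skewness ~ 2/sqrt(2)
        pf_sum = summarize(pf_particles)
        out = merge(pf_sum, Ensemble(enkf_particles, 2, "filtered"),
                    summarize(enkf_particles))
        out_sum = summarize(out.particles)
        se3 = np.sqrt(2.0) * np.sqrt(6.0 / N)
        se4 = np.sqrt(2.0) * np.sqrt(24.0 / N)
        assert abs(out_sum.m3[0] - pf_sum.m3[0]) < 3 * se3 * 3  # gamma inflates
        assert abs(out_sum.m4[0] - pf_sum.m4[0]) < 3 * se4 * 6  # the moment SEs

    def test_particle_pairing_preserved(self):
        """Output particle order is a monotone map of the EnKF ensemble."""
        rng = np.random.default_rng(5)
        enkf_particles = np.sort(rng.standard_normal((500, 1)), axis=0)
        pf_particles = rng.gamma(3.0, size=(500, 1))
        out = merge(summarize(pf_particles),
                    Ensemble(enkf_particles, 2, "filtered"),
                    summarize(enkf_particles))
        assert np.all(np.diff(out.particles[:, 0]) >= 0)


class TestFilter:
    def test_loglik_matches_kalman_on_linear_model(self, chain3,
                                                   linear_params_chain3):
        _, obs = simulate(chain3, linear_params_chain3, T=20, n_series=1,
                          rng_seed=21)
        run = filter_series(obs[0], linear_params_chain3, chain3, N=5000,
                            rng_seed=1)
        *_, ll_exact = oracles.kalman_for(linear_params_chain3, obs[0])
        assert abs(run.loglik - ll_exact) / abs(ll_exact) < 0.02

    def test_filtered_means_match_kalman(self, chain3, linear_params_chain3):
        _, obs = simulate(chain3, linear_params_chain3, T=15, n_series=1,
                          rng_seed=22)
        run = filter_series(obs[0], linear_params_chain3, chain3, N=5000,
                            rng_seed=2)
        _, _, filt_m, filt_P, _ = oracles.kalman_for(linear_params_chain3,
                                                     obs[0])
        for t in (5, 10, 15):
            se = np.sqrt(np.diag(filt_P[t - 1]) / 5000)
            err = np.abs(run.ensembles[t - 1].mean() - filt_m[t - 1])
            assert np.all(err < 3 * se * 2)  # resampling inflates MC error

    def test_reproducible_loglik(self, chain3, linear_params_chain3):
        _, obs = simulate(chain3, linear_params_chain3, T=10, n_series=1,
                          rng_seed=23)
        a = filter_series(obs[0], linear_params_chain3, chain3, 300, 5)
        b = filter_series(obs[0], linear_params_chain3, chain3, 300, 5)
        assert a.loglik == b.loglik

    def test_particle_count_constant_throughout(self):
        s, params = make_quadratic_params()
        _, obs = simulate(s, params, T=12, n_series=1, rng_seed=24)
        run = filter_series(obs[0], params, s, N=250, rng_seed=3)
        assert all(e.N == 250 for e in run.ensembles)
        sm = smooth(run, params, s)
        assert all(e.N == 250 for e in sm)

    def test_removing_informative_edge_lowers_loglik(self, chain3,
                                                     linear_params_chain3):
        """Dropping the 0 -> 1 edge from the generating model hurts fit."""
        deltas = []
        for seed in range(5):
            _, obs = simulate(chain3, linear_params_chain3, T=25, n_series=1,
                              rng_seed=100 + seed)
            full = filter_series(obs[0], linear_params_chain3, chain3, 800,
                                 seed)
            pruned_struct = NetworkStructure(p=3, linear_sets=[set(), set(),
                                                               {1}])
            pruned_params = linear_params_chain3.copy()
            pruned_params.a[1, 0] = 0.0
            pruned = filter_series(obs[0], pruned_params, pruned_struct, 800,
                                   seed)
            deltas.append(full.loglik - pruned.loglik)
        assert np.mean(deltas) > 0

    def test_missing_timepoints_only_predict(self, chain3,
                                             linear_params_chain3):
        _, obs = simulate(chain3, linear_params_chain3, T=12, n_series=1,
                          rng_seed=25, observed_times=[1, 4, 8, 12])
        run = filter_series(obs[0], linear_params_chain3, chain3, 400, 7)
        assert set(run.pf_summaries) == {1, 4, 8, 12}
        assert len(run.per_time_loglik) == 4


class TestSmooth:
    def test_final_time_equals_filtered(self, chain3, linear_params_chain3):
        _, obs = simulate(chain3, linear_params_chain3, T=10, n_series=1,
                          rng_seed=30)
        run = filter_series(obs[0], linear_params_chain3, chain3, 400, 11)
        sm = smooth(run, linear_params_chain3, chain3)
        np.testing.assert_array_equal(sm[-1].particles,
                                      run.ensembles[-1].particles)

    def test_means_match_rts_on_linear_model(self, chain3,
                                             linear_params_chain3):
        _, obs = simulate(chain3, linear_params_chain3, T=15, n_series=1,
                          rng_seed=31)
        N = 5000
        run = filter_series(obs[0], linear_params_chain3, chain3, N, 12)
        sm = smooth(run, linear_params_chain3, chain3)
        pred_m, pred_P, filt_m, filt_P, _ = oracles.kalman_for(
            linear_params_chain3, obs[0])
        sm_m, sm_P = oracles.rts_smoother(pred_m, pred_P, filt_m, filt_P,
                                          oracles.full_linear_matrix(
                                              linear_params_chain3))
        for t in range(0, 15, 3):
            se = np.sqrt(np.diag(sm_P[t]) / N)
            err = np.abs(sm[t].particles.mean(axis=0) - sm_m[t])
            assert np.all(err < 3 * se * 2)

    def test_smoothing_reduces_variance(self, chain3, linear_params_chain3):
        _, obs = simulate(chain3, linear_params_chain3, T=15, n_series=1,
                          rng_seed=32)
        run = filter_series(obs[0], linear_params_chain3, chain3, 4000, 13)
        sm = smooth(run, linear_params_chain3, chain3)
        for t in range(0, 14, 4):
            filt_var = run.ensembles[t].particles.var(axis=0)
            sm_var = sm[t].particles.var(axis=0)
            assert np.all(sm_var <= filt_var + 0.05 * filt_var + 1e-3)
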