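"""Particle filter mechanics and agreement with the grid-Bayes oracle."""

import collections
import math

import numpy as np
import pytest

from lungpf import (
    ClassLabel,
    FilterConfig,
    ParticleSet,
    SyntheticConfig,
    check_convergence,
    compute_weights,
    effective_sample_size,
    generate_cohort,
    grid_posterior,
    posterior_mean,
    run_filter,
    systematic_resample,
)
from lungpf.cohort_io import Trajectory
from lungpf.likelihood import combined_likelihood, combined_likelihood_rows
from lungpf.measurement_model import predict_feature_matrix
from lungpf.synthetic import features_for_state


def uniform_particles(states):
    states = np.asarray(states, dtype=float)
    return ParticleSet(states=states, weights=np.full(states.size, 1.0 / states.size))


def constant_state_trajectory(u, K=5, nodule_id="T"):
    cfg = SyntheticConfig(feature_noise_sd=0.0, state_noise_sd=0.0)
    z = features_for_state(u, cfg, np.random.default_rng(0))
    return Trajectory(nodule_id=nodule_id, points=[z] * K)


class TestParticleSet:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ParticleSet(states=np.array([0.5]), weights=np.array([1.0]))
        with pytest.raises(ValueError):
            ParticleSet(states=np.array([0.5, 1.5]), weights=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            ParticleSet(states=np.array([0.5, 0.6]), weights=np.array([0.5, 0.6]))


class TestComputeWeights:
    def test_matches_explicit_kernel_formula(self, fitted_model, lik_cfg):
        """Oracle: the Gaussian kernel on likelihood discrepancies, written out."""
        sigma = 0.05
        obs = features_for_state(0.4, SyntheticConfig(feature_noise_sd=0, state_noise_sd=0),
                                 np.random.default_rng(0))
        ps = uniform_particles([0.1, 0.35, 0.4, 0.45, 0.9])
        updated = compute_weights(ps, obs, fitted_model, lik_cfg, sigma)
        L_obs, _ = combined_likelihood(obs, lik_cfg)
        L_pred = combined_likelihood_rows(predict_feature_matrix(ps.states, fitted_model), lik_cfg)
        expected = np.exp(-((L_pred - L_obs) ** 2) / (2 * sigma**2))
        expected /= expected.sum()
        np.testing.assert_allclose(updated.weights, expected, rtol=1e-12)
        # the particle at the true state gets the largest weight
        assert np.argmax(updated.weights) == 2

    def test_normalization_and_symmetry(self, fitted_model, lik_cfg):
        obs = features_for_state(0.3, SyntheticConfig(feature_noise_sd=0, state_noise_sd=0),
                                 np.random.default_rng(0))
        ps = uniform_particles(np.linspace(0, 1, 64))
        updated = compute_weights(ps, obs, fitted_model, lik_cfg, 0.05)
        assert updated.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_weights_reset_uniform(self, fitted_model, lik_cfg, caplog):
        obs = features_for_state(0.9, SyntheticConfig(feature_noise_sd=0, state_noise_sd=0),
                                 np.random.default_rng(0))
        ps = uniform_particles([0.0, 0.01])
        with caplog.at_level("WARNING"):
            updated = compute_weights(ps, obs, fitted_model, lik_cfg, sigma_w=1e-6)
        assert "degenerate" in caplog.text
        np.testing.assert_allclose(updated.weights, [0.5, 0.5])


class TestEffectiveSampleSize:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 4.0),
            ([1.0, 0.0, 0.0], 1.0),
            ([0.5, 0.25, 0.25], 1.0 / 0.375),
        ],
    )
    def test_closed_form(self, weights, expected):
        ps = ParticleSet(states=np.linspace(0.1, 0.9, len(weights)), weights=np.array(weights))
        assert effective_sample_size(ps) == pytest.approx(expected, rel=1e-12)


class TestSystematicResample:
    def test_expected_counts_for_three_quarters_weight(self):
        """Ancestor counts are (3, 1) for every uniform offset at Ns=4."""
        for seed in range(25):
            ps = ParticleSet(states=np.array([0.0, 1.0]), weights=np.array([0.75, 0.25]))
            out = systematic_resample(ps, np.random.default_rng(seed), n_out=4)
            counts = collections.Counter(out.states)
            assert counts[0.0] == 3 and counts[1.0] == 1

    def test_uniform_weights_near_identity(self):
        n = 100
        ps = uniform_particles(np.arange(n) / n)
        out = systematic_resample(ps, np.random.default_rng(0))
        counts = collections.Counter(out.states)
        assert all(abs(c - 1) <= 1 for c in counts.values())

    def test_mean_preserved_within_sampling_error(self):
        rng = np.random.default_rng(3)
        n = 4000
        w = rng.random(n)
        ps = ParticleSet(states=rng.random(n), weights=w / w.sum())
        pre = posterior_mean(ps)
        for seed in range(10):
            post = posterior_mean(systematic_resample(ps, np.random.default_rng(seed)))
            assert abs(post - pre) <= 2.0 / math.sqrt(n)

    def test_output_weights_uniform(self):
        ps = ParticleSet(states=np.array([0.2, 0.8]), weights=np.array([0.9, 0.1]))
        out = systematic_resample(ps, np.random.default_rng(1))
        np.testing.assert_allclose(out.weights, 0.5)


class TestPosteriorMean:
    @pytest.mark.parametrize(
        "states, weights, expected",
        [
            ([0.0, 1.0], [0.5, 0.5], 0.5),
            ([0.2, 0.8], [0.75, 0.25], 0.35),
            ([0.63, 0.1], [1.0, 0.0], 0.63),
        ],
    )
    def test_weighted_mean(self, states, weights, expected):
        ps = ParticleSet(states=np.array(states), weights=np.array(weights))
        assert posterior_mean(ps) == pytest.approx(expected, rel=1e-12)


class TestCheckConvergence:
    def test_arithmetic(self):
        assert check_convergence([0.1] * 5, [0.1] * 5, xi=1e-9)
        # per-interval differences of 0.25 everywhere: MSE is exactly 0.0625
        diffs = [0.0] * 5, [0.25] * 5
        assert not check_convergence(*diffs, xi=0.03)
        assert check_convergence(*diffs, xi=0.0625)  # boundary inclusive
        with pytest.raises(ValueError):
            check_convergence([0.1] * 4, [0.1] * 5, xi=0.01)


class TestFilterConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(n_particles=1)
        with pytest.raises(ValueError):
            FilterConfig(sigma_w=0.0)
        with pytest.raises(ValueError):
            FilterConfig(ess_fraction=0.0)
        with pytest.raises(ValueError):
            FilterConfig(K=1)
        with pytest.raises(ValueError):
            FilterConfig(alpha=-1.0)


class TestRunFilter:
    def test_recovers_constant_benign_state(self, fitted_model, lik_cfg):
        traj = constant_state_trajectory(0.30)
        res = run_filter(traj, fitted_model, lik_cfg, FilterConfig(seed=5))
        assert res.label is ClassLabel.BENIGN
        assert abs(res.final_score - 0.30) <= 0.05
        assert res.converged and len(res.pme_per_interval) == 5
        assert all(0 <= v <= 1 for v in res.pme_per_interval)

    def test_advanced_ramp_recovered(self, fitted_model, lik_cfg):
        cfg = SyntheticConfig(feature_noise_sd=0.0, state_noise_sd=0.0)
        rng = np.random.default_rng(0)
        states = np.linspace(0.55, 0.85, 5)
        points = [features_for_state(u, cfg, rng) for u in states]
        traj = Trajectory(nodule_id="ramp", points=points)
        res = run_filter(traj, fitted_model, lik_cfg, FilterConfig(seed=9))
        assert res.label is ClassLabel.ADVANCED_STAGE

    def test_wrong_length_rejected(self, fitted_model, lik_cfg):
        traj = constant_state_trajectory(0.3, K=4)
        with pytest.raises(ValueError, match="interval"):
            run_filter(traj, fitted_model, lik_cfg, FilterConfig(seed=1))

    def test_model_order_mismatch_rejected(self, fitted_model, lik_cfg):
        traj = constant_state_trajectory(0.3)
        with pytest.raises(ValueError, match="order"):
            run_filter(traj, fitted_model, lik_cfg, FilterConfig(seed=1, M=2))

    def test_bitwise_determinism(self, fitted_model, lik_cfg):
        traj = constant_state_trajectory(0.62)
        cfg = FilterConfig(seed=77, n_particles=800)
        r1 = run_filter(traj, fitted_model, lik_cfg, cfg)
        r2 = run_filter(traj, fitted_model, lik_cfg, cfg)
        assert r1.pme_per_interval == r2.pme_per_interval
        assert r1.final_score == r2.final_score
        assert r1.ess_trace == r2.ess_trace
        assert r1.outer_iterations == r2.outer_iterations

    def test_nonconvergence_is_flagged_not_raised(self, fitted_model, lik_cfg):
        traj = constant_state_trajectory(0.3)
        cfg = FilterConfig(seed=3, n_particles=16, xi=1e-12, max_outer_iters=2)
        res = run_filter(traj, fitted_model, lik_cfg, cfg)
        assert res.converged is False
        assert res.outer_iterations == 2


class TestGridOracle:
    def test_flat_likelihood_traces_prior_mean(self, fitted_model, lik_cfg):
        traj = constant_state_trajectory(0.3)
        pme = grid_posterior(traj, fitted_model, lik_cfg, FilterConfig(sigma_w=1e9), n_grid=501)
        np.testing.assert_allclose(pme, 0.5, atol=1e-6)

    def test_grid_refinement_self_consistency(self, fitted_model, lik_cfg):
        traj = constant_state_trajectory(0.62)
        cfg = FilterConfig(seed=1)
        g1 = grid_posterior(traj, fitted_model, lik_cfg, cfg, n_grid=501)
        g2 = grid_posterior(traj, fitted_model, lik_cfg, cfg, n_grid=2001)
        assert np.max(np.abs(np.array(g1) - np.array(g2))) <= 1e-3

    def test_small_grid_rejected(self, fitted_model, lik_cfg):
        traj = constant_state_trajectory(0.3)
        with pytest.raises(ValueError):
            grid_posterior(traj, fitted_model, lik_cfg, FilterConfig(), n_grid=50)

    def test_filter_matches_grid_on_sample_trajectories(self, fitted_model, lik_cfg):
        cohort = generate_cohort(
            SyntheticConfig(n_benign=2, n_early=2, n_advanced=2,
                            state_noise_sd=0.01, feature_noise_sd=0.01, seed=5)
        )
        for i, traj in enumerate(cohort):
            cfg = FilterConfig(seed=300 + i)
            res = run_filter(traj, fitted_model, lik_cfg, cfg)
            grid = grid_posterior(traj, fitted_model, lik_cfg, cfg, n_grid=1001)
            assert np.max(np.abs(np.array(res.pme_per_interval) - np.array(grid))) <= 0.02
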