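"""POBDS generative model: transitions, observations, matrices, steady state."""

import numpy as np
import pytest

from pobds import (
    CapabilityError,
    PobdsModel,
    Trajectory,
    parse_rules,
    read_trajectory_csv,
    sample_observation,
    sample_steady_states,
    simulate_trajectories,
    simulate_trajectory,
    steady_state,
    step_state,
    tlgl_network,
    transition_matrix,
    update_diagonal,
    write_trajectory_csv,
)
from tests.conftest import random_model


class TestModelValidation:
    def test_p_out_of_range_rejected(self, toy3_net):
        for bad in (0.0, 0.5, 0.7, -0.1):
            with pytest.raises(ValueError):
                PobdsModel(toy3_net, p=bad, lam=10, delta=30, sigma=20)

    def test_nb_requires_overdispersion(self, toy3_net):
        with pytest.raises(ValueError, match="overdispersion"):
            PobdsModel(toy3_net, p=0.1, lam=10, delta=30, sigma=6.0,
                       noise_family="negative_binomial")
        PobdsModel(toy3_net, p=0.1, lam=10, delta=30, sigma=7.0,
                   noise_family="negative_binomial")  # 49 > 40: fine


class TestStepState:
    def test_noiseless_limit_is_deterministic_update(self, toy3_net, rng):
        model = PobdsModel(toy3_net, p=1e-12, lam=10, delta=30, sigma=20)
        x = rng.random((1000, 3)) < 0.5
        assert np.array_equal(step_state(model, x, rng), model.net.evaluate(x))

    def test_constant_off_gene_turns_on_with_probability_p(self, unit_model, rng):
        x = np.zeros((100_000, 1), bool)
        frac = step_state(unit_model, x, rng).mean()
        sd = np.sqrt(0.1 * 0.9 / 100_000)
        assert abs(frac - 0.1) < 3 * sd

    def test_flip_counts_binomial(self, toy3_model, rng):
        x = rng.random((50_000, 3)) < 0.5
        flips = (step_state(toy3_model, x, rng) ^ toy3_model.net.evaluate(x)).sum(1)
        p, n = toy3_model.p, 3
        mean, var = n * p, n * p * (1 - p)
        assert abs(flips.mean() - mean) < 4 * np.sqrt(var / 50_000)
        assert abs(flips.var() - var) < 0.02


class TestObservations:
    def test_gaussian_moments_at_default_parameters(self, unit_model, rng):
        y = sample_observation(unit_model, np.ones((100_000, 1), bool), rng)
        assert abs(y.mean() - 40.0) < 0.3  # lambda + delta
        assert abs(y.std() - 20.0) < 0.3  # sigma

    def test_sigma_to_zero_limit(self, toy3_net, rng):
        model = PobdsModel(toy3_net, p=0.1, lam=10, delta=30, sigma=1e-12)
        x = np.array([True, False, True])
        y = sample_observation(model, x, rng)
        np.testing.assert_allclose(y, [40.0, 10.0, 40.0], atol=1e-9)

    def test_poisson_equidispersion(self, toy3_net, rng):
        model = PobdsModel(toy3_net, p=0.1, lam=10, delta=30, noise_family="poisson")
        y = sample_observation(model, np.zeros((100_000, 3), bool), rng)
        assert abs(y.mean() - 10.0) < 0.1
        assert abs(y.var() - 10.0) < 0.3

    def test_nb_moment_match(self, toy3_net, rng):
        model = PobdsModel(toy3_net, p=0.1, lam=10, delta=30, sigma=9.0,
                           noise_family="negative_binomial")
        y = sample_observation(model, np.ones((200_000, 3), bool), rng)
        assert abs(y.mean() - 40.0) < 0.2
        assert abs(y.var() - 81.0) < 2.0


class TestTransitionMatrix:
    def test_one_gene_identity_hand_value(self):
        model = PobdsModel(parse_rules("A = A"), p=0.1, lam=10, delta=30, sigma=20)
        np.testing.assert_allclose(
            transition_matrix(model), [[0.9, 0.1], [0.1, 0.9]], atol=1e-15
        )

    def test_two_gene_identity_hand_values(self):
        model = PobdsModel(parse_rules("A = A\nB = B"), p=0.1, lam=10, delta=30, sigma=20)
        M = transition_matrix(model)
        assert M[0, 0] == pytest.approx(0.81)
        assert M[1, 0] == pytest.approx(0.09)
        assert M[3, 0] == pytest.approx(0.01)

    def test_columns_sum_to_one(self, rng):
        for k in range(5):
            model = random_model(np.random.default_rng(100 + k), n=5)
            M = transition_matrix(model)
            np.testing.assert_allclose(M.sum(0), 1.0, atol=1e-12)
            assert (M > 0).all()  # irreducible/aperiodic for 0<p<0.5

    def test_near_half_p_is_near_uniform(self, toy3_net):
        model = PobdsModel(toy3_net, p=0.499, lam=10, delta=30, sigma=20)
        np.testing.assert_allclose(transition_matrix(model), 1 / 8, atol=1e-3)

    def test_guard_refuses_18_genes(self):
        model = PobdsModel(tlgl_network(), p=0.05, lam=10, delta=30, sigma=20)
        with pytest.raises(CapabilityError, match="particle"):
            transition_matrix(model)


class TestUpdateDiagonal:
    def test_one_gene_hand_values(self, unit_model):
        d = update_diagonal(unit_model, np.array([40.0]))
        assert d[1] == pytest.approx(0.0199471, abs=1e-6)
        assert d[0] == pytest.approx(0.0064766, abs=1e-6)

    def test_exact_observation_maximizes_own_state(self, toy3_model):
        from pobds import all_states

        for i, x in enumerate(all_states(3)):
            y = toy3_model.lam + toy3_model.delta * x
            d = update_diagonal(toy3_model, y)
            assert d.argmax() == i

    def test_larger_sigma_flattens_ratios(self, toy3_net):
        y = np.full(3, 10.0)
        m1 = PobdsModel(toy3_net, p=0.1, lam=10, delta=30, sigma=20)
        m2 = PobdsModel(toy3_net, p=0.1, lam=10, delta=30, sigma=40)
        r1 = update_diagonal(m1, y)
        r2 = update_diagonal(m2, y)
        assert (r2 / r2.max()).min() > (r1 / r1.max()).min()

    def test_gene_permutation_invariance(self, toy3_model, rng):
        perm = np.array([2, 0, 1])
        pm = PobdsModel(
            toy3_model.net.permuted(perm), p=toy3_model.p,
            lam=toy3_model.lam[perm], delta=toy3_model.delta[perm],
            sigma=toy3_model.sigma,
        )
        y = rng.normal(25, 15, 3)
        d = update_diagonal(toy3_model, y)
        dp = update_diagonal(pm, y[perm])
        # state i under original encoding maps to a permuted index
        from pobds import all_states, pack_states

        mapped = pack_states(all_states(3)[:, perm])
        np.testing.assert_allclose(dp[mapped], d, rtol=1e-12)

    def test_non_gaussian_family_refused(self, toy3_net):
        model = PobdsModel(toy3_net, p=0.1, lam=10, delta=30, noise_family="poisson")
        with pytest.raises(CapabilityError):
            update_diagonal(model, np.full(3, 10.0))


class TestSteadyState:
    def test_one_gene_constant_off(self, unit_model):
        np.testing.assert_allclose(steady_state(unit_model).probs, [0.9, 0.1], atol=1e-12)

    def test_stationarity_residual(self):
        for k in range(4):
            model = random_model(np.random.default_rng(200 + k), n=6)
            pi = steady_state(model).probs
            M = transition_matrix(model)
            assert np.abs(M @ pi - pi).sum() < 1e-10

    def test_near_half_p_near_uniform(self, toy3_net):
        model = PobdsModel(toy3_net, p=0.499, lam=10, delta=30, sigma=20)
        np.testing.assert_allclose(steady_state(model).probs, 1 / 8, atol=1e-3)

    def test_monte_carlo_close_to_exact(self, rng):
        model = random_model(np.random.default_rng(33), n=6)
        mc = steady_state(model, "monte_carlo", rng, n_samples=100_000)
        tv = 0.5 * np.abs(mc.probs - steady_state(model).probs).sum()
        assert tv < 0.02

    def test_sampler_matches_exact_distribution(self, rng):
        model = random_model(np.random.default_rng(44), n=5)
        draws = sample_steady_states(model, 100_000, rng)
        from pobds import pack_states

        freq = np.bincount(pack_states(draws), minlength=32) / 100_000
        tv = 0.5 * np.abs(freq - steady_state(model).probs).sum()
        assert tv < 0.02


class TestSimulation:
    def test_single_step_trajectory_shape(self, toy3_model, rng):
        traj = simulate_trajectory(toy3_model, 1, rng)
        assert traj.y.shape == (1, 3) and traj.x.shape == (1, 3)

    def test_seeded_reproducibility(self, toy3_model):
        t1 = simulate_trajectory(toy3_model, 5, np.random.default_rng(9))
        t2 = simulate_trajectory(toy3_model, 5, np.random.default_rng(9))
        np.testing.assert_array_equal(t1.y, t2.y)
        np.testing.assert_array_equal(t1.x, t2.x)

    def test_long_run_visit_frequencies_match_steady_state(self, rng):
        model = random_model(np.random.default_rng(55), n=4, p=0.05)
        Y, X = simulate_trajectories(model, 1, 100_000, rng)
        from pobds import pack_states, steady_state as ss

        freq = np.bincount(pack_states(X[0]), minlength=16) / X.shape[1]
        tv = 0.5 * np.abs(freq - ss(model).probs).sum()
        assert tv < 0.05


class TestTrajectoryCsv:
    def test_round_trip_bit_exact(self, toy3_model, rng, tmp_path):
        traj = simulate_trajectory(toy3_model, 7, rng)
        ypath, xpath = tmp_path / "y.csv", tmp_path / "x.csv"
        write_trajectory_csv(traj, ypath, toy3_model.net.gene_names, states_path=xpath)
        back = read_trajectory_csv(ypath, states_path=xpath)
        np.testing.assert_array_equal(back.y, traj.y)
        np.testing.assert_array_equal(back.x, traj.x)
        assert back.meta["gene_names"] == list(toy3_model.net.gene_names)
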