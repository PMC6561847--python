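"""OBC / IBR / Plug-In classifiers and the multiple-cell mixture rules."""

import numpy as np
import pytest

from pobds import (
    ExactEngine,
    PobdsModel,
    Trajectory,
    TrainingSet,
    UncertaintyClass,
    fit_posterior,
    ibr_classify,
    multicell_log_density,
    multicell_obc,
    obc_classify,
    plugin_classify,
    sample_multicell,
    simulate_trajectory,
    state_on_marginals,
    steady_state,
)
from tests.conftest import random_model


def _toy_uc(M=2, p0=0.5, seed=0, n=3):
    gen = np.random.default_rng(seed)
    models0 = [random_model(np.random.default_rng(gen.integers(1 << 30)), n=n, p=0.1)
               for _ in range(M)]
    # class-1 models share observation parameters so only dynamics differ
    models1 = [
        PobdsModel(
            random_model(np.random.default_rng(gen.integers(1 << 30)), n=n, p=0.1).net,
            p=0.1, lam=models0[0].lam, delta=models0[0].delta, sigma=models0[0].sigma,
        )
        for _ in range(M)
    ]
    models0 = [PobdsModel(m.net, p=0.1, lam=models0[0].lam, delta=models0[0].delta,
                          sigma=models0[0].sigma) for m in models0]
    return UncertaintyClass((models0, models1), p0=p0)


def _train(uc, d_per_class, seed=0, T=4):
    gen = np.random.default_rng(seed)
    return TrainingSet(tuple(
        [simulate_trajectory(uc.models[c][0], T, gen) for _ in range(d_per_class)]
        for c in (0, 1)
    ))


ENGINE = ExactEngine()


class TestFitPosterior:
    def test_identical_models_recover_prior(self):
        uc = _toy_uc(M=1)
        uc3 = UncertaintyClass((uc.models[0] * 3, uc.models[1] * 3),
                               prior=(np.array([0.5, 0.3, 0.2]),
                                      np.array([0.2, 0.3, 0.5])))
        post = fit_posterior(uc3, _train(uc3, 3), ENGINE)
        np.testing.assert_allclose(post.posterior[0], [0.5, 0.3, 0.2], atol=1e-10)
        np.testing.assert_allclose(post.posterior[1], [0.2, 0.3, 0.5], atol=1e-10)

    def test_two_model_softmax_closed_form(self):
        uc = _toy_uc(M=2, seed=3)
        post = fit_posterior(uc, _train(uc, 2, seed=4), ENGINE)
        for c in (0, 1):
            delta = post.log_marginals[c, 0] - post.log_marginals[c, 1]
            expect = 1.0 / (1.0 + np.exp(-delta))
            assert post.posterior[c, 0] == pytest.approx(expect, abs=1e-10)

    def test_empty_training_degrades_to_prior(self):
        uc = _toy_uc(M=3, seed=5)
        post = fit_posterior(uc, TrainingSet(([], [])), ENGINE)
        np.testing.assert_allclose(post.posterior, np.stack(uc.prior), atol=1e-12)

    def test_posterior_consistency_with_growing_data(self):
        """The generating model's weight approaches 1 as D grows."""
        uc = _toy_uc(M=2, seed=11, n=4)
        post = fit_posterior(uc, _train(uc, 32, seed=12, T=6), ENGINE)
        assert post.posterior[0, 0] > 0.9
        assert post.posterior[1, 0] > 0.9

    def test_rows_normalized(self):
        uc = _toy_uc(M=4, seed=13)
        post = fit_posterior(uc, _train(uc, 2, seed=14), ENGINE)
        np.testing.assert_allclose(post.posterior.sum(1), 1.0, atol=1e-10)


class TestDecisionRules:
    def test_m1_collapse_all_rules_agree(self):
        uc = _toy_uc(M=1, seed=21)
        train = _train(uc, 2, seed=22)
        post = fit_posterior(uc, train, ENGINE)
        gen = np.random.default_rng(23)
        for _ in range(10):
            traj = simulate_trajectory(uc.models[gen.integers(2)][0], 4, gen)
            d_obc = obc_classify(uc, post, traj, ENGINE)
            d_ibr = ibr_classify(uc, traj, ENGINE)
            d_plg = plugin_classify(uc, train, traj, ENGINE, post=post)
            assert d_obc.label == d_ibr.label == d_plg.label
            np.testing.assert_allclose(d_obc.log_scores, d_ibr.log_scores, atol=1e-10)

    def test_exact_tie_goes_to_class_zero(self):
        uc = _toy_uc(M=1, seed=31)
        # identical models in both classes -> identical scores -> tie
        sym = UncertaintyClass((uc.models[0], uc.models[0]), p0=0.5)
        traj = simulate_trajectory(sym.models[0][0], 3, np.random.default_rng(32))
        dec = ibr_classify(sym, traj, ENGINE)
        assert dec.log_scores[0] == dec.log_scores[1]
        assert dec.label == 0

    def test_degenerate_class_prior_forces_label(self):
        uc = _toy_uc(M=2, seed=41, p0=1.0)
        traj = simulate_trajectory(uc.models[1][0], 4, np.random.default_rng(42))
        assert ibr_classify(uc, traj, ENGINE).label == 0

    def test_obc_equals_ibr_without_training(self):
        uc = _toy_uc(M=3, seed=51)
        post = fit_posterior(uc, TrainingSet(([], [])), ENGINE)
        gen = np.random.default_rng(52)
        for _ in range(5):
            traj = simulate_trajectory(uc.models[0][0], 3, gen)
            assert (obc_classify(uc, post, traj, ENGINE).label
                    == ibr_classify(uc, traj, ENGINE).label)

    def test_plugin_matches_obc_when_posterior_concentrated(self):
        uc = _toy_uc(M=2, seed=61, n=4)
        train = _train(uc, 24, seed=62, T=6)
        post = fit_posterior(uc, train, ENGINE)
        assert (post.log_marginals.max(1) - post.log_marginals.min(1) > 20).all()
        gen = np.random.default_rng(63)
        for _ in range(10):
            traj = simulate_trajectory(uc.models[gen.integers(2)][0], 4, gen)
            assert (plugin_classify(uc, train, traj, ENGINE, post=post).label
                    == obc_classify(uc, post, traj, ENGINE).label)

    def test_plugin_tie_breaks_to_lowest_index(self):
        uc = _toy_uc(M=1, seed=71)
        dup = UncertaintyClass((uc.models[0] * 2, uc.models[1] * 2))
        train = _train(dup, 2, seed=72)
        post = fit_posterior(dup, train, ENGINE)
        assert post.log_marginals[0, 0] == post.log_marginals[0, 1]
        assert post.log_marginals.argmax(1).tolist() == [0, 0]

    def test_decision_invariant_to_common_within_class_shift(self):
        """Adding a constant to every log-likelihood of one class's models
        shifts tau by that constant in log space; shifting both classes
        equally leaves the decision unchanged."""
        uc = _toy_uc(M=3, seed=81)
        post = fit_posterior(uc, _train(uc, 2, seed=82), ENGINE)
        traj = simulate_trajectory(uc.models[0][0], 4, np.random.default_rng(83))

        class Shifted:
            stochastic = False

            def __init__(self, shift):
                self.shift = shift

            def loglik(self, model, t, rng=None):
                return ENGINE.loglik(model, t) + self.shift

        base = obc_classify(uc, post, traj, ENGINE)
        moved = obc_classify(uc, post, traj, Shifted(37.0))
        assert moved.label == base.label
        np.testing.assert_allclose(
            moved.log_scores - base.log_scores, 37.0, atol=1e-8
        )


class TestMulticell:
    def test_point_mass_steady_state_single_gaussian(self):
        # constant network: all genes forced ON -> q = 1 (up to perturbation)
        model = PobdsModel(
            __import__("pobds").parse_rules("A = 1\nB = 1"), p=0.01,
            lam=10, delta=30, sigma=20,
        )
        q = state_on_marginals(model)
        assert (q > 0.98).all()

    def test_hand_worked_mixture_density(self):
        """q = 0.5 per gene, y midway between the component means."""
        model = PobdsModel(
            __import__("pobds").parse_rules("A = NOT A"), p=0.25,
            lam=10, delta=30, sigma=20,
        )
        q = state_on_marginals(model)
        assert q[0] == pytest.approx(0.5, abs=1e-10)
        dens = np.exp(multicell_log_density(model, np.array([25.0])))
        assert dens == pytest.approx(0.015058, abs=1e-5)

    def test_monte_carlo_marginals_match_exact(self, rng):
        model = random_model(np.random.default_rng(91), n=6)
        q_exact = state_on_marginals(model)
        x = __import__("pobds").sample_steady_states(model, 100_000, rng)
        np.testing.assert_allclose(x.mean(0), q_exact, atol=0.01)

    def test_mixture_mean_matches_steady_state_formula(self):
        """Per-gene mean of simulated multicell samples = lam + delta * q."""
        model = random_model(np.random.default_rng(92), n=5)
        q = state_on_marginals(model)
        y = sample_multicell(model, 200_000, np.random.default_rng(93))
        np.testing.assert_allclose(
            y.mean(0), model.lam + model.delta * q, atol=0.35
        )

    def test_m1_reduces_to_mixture_likelihood_ratio(self):
        uc = _toy_uc(M=1, seed=94)
        y = sample_multicell(uc.models[0][0], 1, np.random.default_rng(95))[0]
        dec = multicell_obc(uc, (np.empty((0, 3)), np.empty((0, 3))), y)
        l0 = multicell_log_density(uc.models[0][0], y)
        l1 = multicell_log_density(uc.models[1][0], y)
        expect = 0 if np.log(0.5) + l0 >= np.log(0.5) + l1 else 1
        assert dec.label == expect

    def test_error_monotone_in_sigma(self):
        """Separation degrades as observation noise grows (distinct steady
        states: class 0 genes mostly ON, class 1 mostly OFF)."""
        parse = __import__("pobds").parse_rules
        nets0 = [parse("A = 1\nB = 1\nC = 1\nD = 1"),
                 parse("A = 1\nB = 1\nC = 1\nD = D")]
        nets1 = [parse("A = 0\nB = 0\nC = 0\nD = 0"),
                 parse("A = 0\nB = 0\nC = 0\nD = D")]
        errors = []
        for sigma in (5.0, 10.0, 20.0, 30.0, 40.0):
            gen = np.random.default_rng(96)
            uc = UncertaintyClass(
                tuple(
                    [PobdsModel(net, p=0.1, lam=10, delta=30, sigma=sigma)
                     for net in nets]
                    for nets in (nets0, nets1)
                )
            )
            wrong = 0
            trials = 300
            for _ in range(trials):
                c = gen.integers(2)
                y = sample_multicell(uc.models[c][0], 1, gen)[0]
                train = tuple(sample_multicell(uc.models[cc][0], 8, gen) for cc in (0, 1))
                wrong += multicell_obc(uc, train, y).label != c
            errors.append(wrong / trials)
        assert errors[0] < errors[-1]
        assert errors[0] < 0.1
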