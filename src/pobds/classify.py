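"""Trajectory classifiers under regulatory-model uncertainty.

The unknown network function for each class (healthy ``c=0`` vs cancerous
``c=1``) is represented by a finite uncertainty class of M candidate POBDS
models with prior weights ``pi(theta | c)``.  Three decision rules share one
likelihood bank:

* **OBC** — optimal Bayesian classifier: the class-conditional density of the
  test trajectory is averaged under the *posterior* over models given the
  training trajectories;
* **IBR** — intrinsically Bayesian robust: the average is taken under the
  *prior* (training data ignored);
* **Plug-In** — pick the maximum-likelihood model per class from training
  data, then apply the Bayes rule at that single model.

All three collapse to the same likelihood-ratio rule when M = 1.  Score
arithmetic is done in log space (log-sum-exp); exact ties in either the model
selection or the class decision resolve deterministically (lowest model
index, class 0).

A second family of rules handles multiple-cell averaged measurements: under
the steady-state distribution each gene's measurement is a two-component
Gaussian mixture with ON-probability ``q_j``, the gene's stationary marginal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .engines import spawn_rng
from .model import (
    MATRIX_GUARD,
    CapabilityError,
    PobdsModel,
    Trajectory,
    sample_observation,
    sample_steady_states,
    steady_state,
)
from .network import all_states

__all__ = [
    "UncertaintyClass",
    "TrainingSet",
    "ModelPosterior",
    "ClassifierDecision",
    "fit_posterior",
    "obc_classify",
    "ibr_classify",
    "plugin_classify",
    "state_on_marginals",
    "multicell_log_density",
    "multicell_obc",
    "sample_multicell",
]


@dataclass
class UncertaintyClass:
    """M candidate POBDS models per class with prior weights."""

    models: tuple  # (models_class0, models_class1), each a sequence of PobdsModel
    prior: Optional[tuple] = None  # (prior_class0, prior_class1); default uniform
    p0: float = 0.5  # prior probability of class 0

    def __post_init__(self):
        m0, m1 = self.models
        self.models = (list(m0), list(m1))
        if len(self.models[0]) != len(self.models[1]) or not self.models[0]:
            raise ValueError("both classes need the same number M >= 1 of models")
        if self.prior is None:
            u = np.full(self.M, 1.0 / self.M)
            self.prior = (u, u.copy())
        else:
            self.prior = tuple(np.asarray(w, dtype=float) for w in self.prior)
            for w in self.prior:
                if w.shape != (self.M,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
                    raise ValueError("each class prior must be M nonnegative weights summing to 1")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")

    @property
    def M(self) -> int:
        return len(self.models[0])


@dataclass
class TrainingSet:
    """Observed training trajectories per class."""

    trajectories: tuple  # (list of Trajectory for class 0, list for class 1)

    def __post_init__(self):
        t0, t1 = self.trajectories
        self.trajectories = (list(t0), list(t1))

    def counts(self):
        return len(self.trajectories[0]), len(self.trajectories[1])


@dataclass
class ModelPosterior:
    """Per-class log marginal likelihoods and normalized posterior weights."""

    log_marginals: np.ndarray  # (2, M)
    posterior: np.ndarray  # (2, M), rows sum to 1

    def __post_init__(self):
        self.log_marginals = np.asarray(self.log_marginals, dtype=float)
        self.posterior = np.asarray(self.posterior, dtype=float)
        if np.any(np.abs(self.posterior.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("posterior rows must sum to 1")


@dataclass
class ClassifierDecision:
    """A binary decision with its per-class log scores."""

    label: int
    log_scores: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.log_scores = np.asarray(self.log_scores, dtype=float)


def _decide(log_scores: np.ndarray) -> ClassifierDecision:
    # ties resolve to class 0 (the decision rule uses ">=")
    label = 0 if log_scores[0] >= log_scores[1] else 1
    return ClassifierDecision(label, log_scores)


def _class_log_priors(p0: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(np.array([p0, 1.0 - p0]))


def _test_logliks(uc, traj, engine, seed):
    """L_c^theta(test) for all (c, theta): shape (2, M)."""
    L = np.empty((2, uc.M))
    for c in (0, 1):
        for m, model in enumerate(uc.models[c]):
            rng = spawn_rng(seed, 1, c, m) if engine.stochastic else None
            L[c, m] = engine.loglik(model, traj, rng)
    return L


def fit_posterior(
    uc: UncertaintyClass,
    train: TrainingSet,
    engine,
    seed: int = 0,
) -> ModelPosterior:
    """Posterior over candidate models given the training trajectories.

    ``log p(theta | Y^c, c) propto sum_d L_c^theta(Y_c^(d)) + log pi(theta|c)``
    computed with log-sum-exp.  An empty class (D_c = 0) degrades to the
    prior, making the OBC coincide with the IBR rule for that class.  For a
    stochastic engine, the filter run for each (class, model, trajectory)
    triple gets its own stream derived from ``seed``.
    """
    log_marg = np.zeros((2, uc.M))
    for c in (0, 1):
        for m, model in enumerate(uc.models[c]):
            for d, traj in enumerate(train.trajectories[c]):
                rng = spawn_rng(seed, 0, c, m, d) if engine.stochastic else None
                log_marg[c, m] += engine.loglik(model, traj, rng)
    posterior = np.empty_like(log_marg)
    for c in (0, 1):
        with np.errstate(divide="ignore"):
            logp = log_marg[c] + np.log(uc.prior[c])
        posterior[c] = np.exp(logp - logsumexp(logp))
        posterior[c] /= posterior[c].sum()
    return ModelPosterior(log_marg, posterior)


def _mixture_decision(uc, weights, traj, engine, seed) -> ClassifierDecision:
    L = _test_logliks(uc, traj, engine, seed)
    with np.errstate(divide="ignore"):
        log_tau = np.array(
            [logsumexp(L[c] + np.log(weights[c])) for c in (0, 1)]
        )
    return _decide(_class_log_priors(uc.p0) + log_tau)


def obc_classify(
    uc: UncertaintyClass,
    post: ModelPosterior,
    test: Trajectory,
    engine,
    seed: int = 0,
) -> ClassifierDecision:
    """Optimal Bayesian classifier: posterior-weighted effective densities."""
    return _mixture_decision(uc, post.posterior, test, engine, seed)


def ibr_classify(
    uc: UncertaintyClass,
    test: Trajectory,
    engine,
    seed: int = 0,
) -> ClassifierDecision:
    """IBR classifier: prior-weighted effective densities (no training)."""
    return _mixture_decision(uc, np.stack(uc.prior), test, engine, seed)


def plugin_classify(
    uc: UncertaintyClass,
    train: TrainingSet,
    test: Trajectory,
    engine,
    seed: int = 0,
    post: Optional[ModelPosterior] = None,
) -> ClassifierDecision:
    """Plug-In classifier: Bayes rule at the per-class ML model.

    Ties in the training log-marginals resolve to the lowest model index.
    ``post`` may supply precomputed log-marginals to avoid refitting.
    """
    if post is None:
        post = fit_posterior(uc, train, engine, seed)
    best = post.log_marginals.argmax(axis=1)  # argmax takes the lowest index on ties
    L = _test_logliks(uc, test, engine, seed)
    scores = _class_log_priors(uc.p0) + np.array([L[0, best[0]], L[1, best[1]]])
    return _decide(scores)


# --------------------------------------------------------------------------
# multiple-cell (steady-state averaged) classification

def state_on_marginals(
    model: PobdsModel,
    rng: Optional[np.random.Generator] = None,
    mc_samples: int = 20_000,
) -> np.ndarray:
    """Per-gene stationary ON-probabilities ``q_j = P(X(j) = 1)``.

    Computed exactly from the stationary vector when ``n <= MATRIX_GUARD``;
    otherwise approximated from Monte-Carlo steady-state draws (requires
    ``rng``).  Cached on the model.
    """
    key = "on_marginals"
    if key in model._cache:
        return model._cache[key]
    if model.n <= MATRIX_GUARD:
        pi = steady_state(model, "exact").probs
        A = all_states(model.n).astype(float)  # (2^n, n)
        q = pi @ A
    else:
        if rng is None:
            raise CapabilityError(
                f"n={model.n} exceeds the matrix guard; pass an rng to "
                "approximate the stationary marginals by Monte Carlo"
            )
        q = sample_steady_states(model, mc_samples, rng).mean(axis=0)
    model._cache[key] = q
    return q


def multicell_log_density(
    model: PobdsModel,
    y: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Log-density of averaged-cell measurements under the mixture model.

    Each gene is a two-component Gaussian mixture,
    ``(1-q_j) N(lambda_j, sigma^2) + q_j N(lambda_j + delta_j, sigma^2)``,
    with ``q_j`` the stationary ON-marginal.  ``y`` may be a single n-vector
    or a batch ``(..., n)``; the gene axis is summed.
    """
    q = state_on_marginals(model, rng)
    y = np.asarray(y, dtype=float)
    s2 = model.sigma**2
    norm = -0.5 * np.log(2 * np.pi * s2)
    log_off = norm - 0.5 * (y - model.lam) ** 2 / s2
    log_on = norm - 0.5 * (y - model.lam - model.delta) ** 2 / s2
    with np.errstate(divide="ignore"):
        comp = np.stack([np.log1p(-q) + log_off, np.log(q) + log_on])
    return logsumexp(comp, axis=0).sum(axis=-1)


def _multicell_bank(uc, Y, rng):
    """log p(Y | theta, c) for each (c, theta) and each row of Y."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    L = np.empty((2, uc.M, Y.shape[0]))
    for c in (0, 1):
        for m, model in enumerate(uc.models[c]):
            L[c, m] = multicell_log_density(model, Y, rng)
    return L


def multicell_obc(
    uc: UncertaintyClass,
    train_samples: Sequence[np.ndarray],
    y: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> ClassifierDecision:
    """OBC for a single multiple-cell averaged measurement ``y``.

    ``train_samples`` holds per-class arrays of shape ``(N_c, n)`` (``N_c``
    may be 0, in which case the posterior degrades to the prior).  The
    posterior over models uses products of the mixture densities of the
    training samples; the decision applies the same ``>=`` tie rule as the
    trajectory OBC.
    """
    log_scores = _class_log_priors(uc.p0).copy()
    for c in (0, 1):
        tr = np.asarray(train_samples[c], dtype=float).reshape(-1, uc.models[c][0].n)
        log_marg = np.zeros(uc.M)
        for m, model in enumerate(uc.models[c]):
            if tr.shape[0]:
                log_marg[m] = multicell_log_density(model, tr, rng).sum()
        with np.errstate(divide="ignore"):
            logw = log_marg + np.log(uc.prior[c])
        logw -= logsumexp(logw)
        Ltest = np.array(
            [multicell_log_density(model, y, rng) for model in uc.models[c]]
        )
        log_scores[c] += logsumexp(Ltest + logw)
    return _decide(log_scores)


def sample_multicell(
    model: PobdsModel,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``size`` independent multiple-cell measurements.

    Each sample's latent state is an independent steady-state draw pushed
    through the observation channel, matching the mixture model's
    independence assumption.
    """
    x = sample_steady_states(model, size, rng)
    return sample_observation(model, x, rng)
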