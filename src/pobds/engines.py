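"""Likelihood engines: a uniform interface over exact and particle filters.

The classifiers are agnostic to how ``L_c^theta(Y_{1:T})`` is computed.  An
engine exposes

* ``loglik(model, traj, rng=None) -> float``
* ``loglik_batch(model, Y, rng=None) -> (R,) array`` for ``Y`` of shape
  ``(R, T, n)`` (independent trajectories, vectorized),

plus a ``stochastic`` flag.  Particle engines require an explicit
``numpy.random.Generator``; reproducible per-(model, trajectory) streams can
be derived from a root seed with :func:`spawn_rng`, which hashes a structured
integer key through :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import numpy as np

from .exact import exact_log_likelihood
from .model import PobdsModel, Trajectory
from .particle import (
    apf_log_likelihood_batch,
    sir_log_likelihood_batch,
)

__all__ = ["spawn_rng", "ExactEngine", "ApfEngine", "SirEngine", "make_engine"]


def spawn_rng(root_seed: int, *key: int) -> np.random.Generator:
    """Derive an independent generator from ``root_seed`` and an integer key.

    The same ``(root_seed, key)`` always yields the same stream; distinct keys
    yield statistically independent streams (SeedSequence spawn-key
    semantics).  Used to give every (class, model, trajectory) filter run in a
    bank its own reproducible randomness.
    """
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=tuple(key)))


class ExactEngine:
    """Matrix BKF likelihood — exact, deterministic, needs n <= guard."""

    stochastic = False

    def loglik(self, model: PobdsModel, traj: Trajectory, rng=None) -> float:
        return exact_log_likelihood(model, traj)[0]

    def loglik_batch(self, model: PobdsModel, Y: np.ndarray, rng=None) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        return np.array([exact_log_likelihood(model, Trajectory(y))[0] for y in Y])


class ApfEngine:
    """Auxiliary-particle-filter BKF likelihood — O(NT), any network size."""

    stochastic = True

    def __init__(self, n_particles: int = 1000, resampling: str = "multinomial"):
        self.n_particles = int(n_particles)
        self.resampling = resampling

    def loglik(self, model, traj: Trajectory, rng=None) -> float:
        return float(self.loglik_batch(model, traj.y[None], rng)[0])

    def loglik_batch(self, model, Y, rng=None) -> np.ndarray:
        if rng is None:
            raise ValueError("particle engines require an explicit rng")
        return apf_log_likelihood_batch(
            model, Y, self.n_particles, rng, resampling=self.resampling
        )


class SirEngine:
    """Plain bootstrap-filter likelihood — the no-look-ahead baseline."""

    stochastic = True

    def __init__(self, n_particles: int = 1000):
        self.n_particles = int(n_particles)

    def loglik(self, model, traj: Trajectory, rng=None) -> float:
        return float(self.loglik_batch(model, traj.y[None], rng)[0])

    def loglik_batch(self, model, Y, rng=None) -> np.ndarray:
        if rng is None:
            raise ValueError("particle engines require an explicit rng")
        return sir_log_likelihood_batch(model, Y, self.n_particles, rng)


def make_engine(name: str, n_particles: int = 1000):
    """Build an engine by name: ``exact``, ``apf`` or ``sir``."""
    if name == "exact":
        return ExactEngine()
    if name == "apf":
        return ApfEngine(n_particles)
    if name == "sir":
        return SirEngine(n_particles)
    raise ValueError(f"unknown engine {name!r}")
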