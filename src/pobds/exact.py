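"""Exact trajectory log-likelihood via the Boolean Kalman filter.

The BKF is the exact recursive filter over the ``2^n`` state probabilities of
a POBDS.  Writing ``M`` for the transition matrix and ``T_k`` for the diagonal
update matrix of observation densities at time ``k``, the filtered belief is

    Pi_{k|k} = T_k M Pi_{k-1|k-1} / || T_k M Pi_{k-1|k-1} ||_1

and the trajectory log-likelihood is the sum of the log L1 normalizers.  The
recursion here is the scaled forward algorithm: beliefs are renormalized every
step, so the per-step normalizers never underflow for realistic horizons even
though their product does.

``brute_force_log_likelihood`` is an independent enumeration oracle (explicit
sum over all latent state sequences) used to validate the recursion on tiny
problems.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    BeliefVector,
    PobdsModel,
    Trajectory,
    log_obs_density,
    steady_state,
    transition_matrix,
    update_diagonal,
)
from .network import all_states

__all__ = [
    "FilterTrace",
    "bkf_step",
    "exact_log_likelihood",
    "brute_force_log_likelihood",
]


@dataclass
class FilterTrace:
    """Per-step record of a BKF run: filtered beliefs and log normalizers."""

    beliefs: list  # BeliefVector per step, k = 1..T
    log_increments: np.ndarray  # (T,) log ||T_k M Pi_{k-1|k-1}||_1
    log_likelihood: float = field(init=False)

    def __post_init__(self):
        self.log_increments = np.asarray(self.log_increments, dtype=float)
        self.log_likelihood = float(self.log_increments.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"step": np.arange(1, len(self.log_increments) + 1),
             "log_increment": self.log_increments}
        ).to_csv(path, index=False)


def bkf_step(belief: BeliefVector, M: np.ndarray, d: np.ndarray):
    """One predict-update step of the Boolean Kalman filter.

    Returns ``(posterior_belief, log_increment)`` where the increment is
    ``log || d o (M @ belief) ||_1``, the contribution of this observation to
    the trajectory log-likelihood.
    """
    d = np.asarray(d, dtype=float)
    u = d * (M @ belief.probs)
    s = u.sum()
    if not s > 0.0:
        raise FloatingPointError(
            "BKF normalizer underflowed to zero; observation density is "
            "degenerate for every state (check sigma and the observation scale)"
        )
    return BeliefVector(u / s), float(np.log(s))


def exact_log_likelihood(
    model: PobdsModel,
    traj: Trajectory,
    prior: Optional[BeliefVector] = None,
):
    """Exact log-likelihood of a trajectory under a POBDS model.

    ``prior`` is the time-0 belief; it defaults to the chain's exact steady
    state.  Returns ``(log_likelihood, FilterTrace)``.  Requires the Gaussian
    observation family and ``n <= MATRIX_GUARD`` (the matrices involved have
    ``2^{2n}`` entries — the reason the particle engine exists).
    """
    M = transition_matrix(model)
    if prior is None:
        prior = steady_state(model, "exact")
    belief = prior
    increments = np.empty(traj.T)
    beliefs = []
    for k in range(traj.T):
        d = update_diagonal(model, traj.y[k])
        belief, increments[k] = bkf_step(belief, M, d)
        beliefs.append(belief)
    trace = FilterTrace(beliefs, increments)
    return trace.log_likelihood, trace


def brute_force_log_likelihood(
    model: PobdsModel,
    traj: Trajectory,
    prior: Optional[BeliefVector] = None,
) -> float:
    """Enumeration oracle: ``log sum over all latent state sequences``.

    Sums ``prior(x_0) * prod_k P(x_k | x_{k-1}) * prod_k p(y_k | x_k)`` over
    every sequence ``(x_0, .., x_T)`` by explicit iteration, independently of
    the filter recursion.  Restricted to ``n * T <= 20``.
    """
    n, T = model.n, traj.T
    if n * T > 20:
        raise ValueError(f"enumeration bound exceeded: n*T = {n * T} > 20")
    S = 1 << n
    states = all_states(n)
    if prior is None:
        prior = steady_state(model, "exact")
    pri = prior.probs
    # plain per-entry transition probabilities and observation densities
    fx = model.net.evaluate(states)
    trans = np.empty((S, S))
    for j in range(S):
        for i in range(S):
            dist = int(np.sum(fx[j] ^ states[i]))
            trans[i, j] = model.p**dist * (1.0 - model.p) ** (n - dist)
    obs = np.empty((T, S))
    for k in range(T):
        for i in range(S):
            obs[k, i] = math.exp(float(log_obs_density(model, traj.y[k], states[i])))
    total = 0.0
    for seq in itertools.product(range(S), repeat=T + 1):
        prob = pri[seq[0]]
        for k in range(1, T + 1):
            prob *= trans[seq[k], seq[k - 1]] * obs[k - 1, seq[k]]
        total += prob
    return math.log(total)
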