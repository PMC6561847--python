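"""The POBDS generative model.

A partially-observed Boolean dynamical system couples a Boolean network
Markov chain with a continuous observation channel:

* state transition: ``X_k = f(X_{k-1}) XOR n_k`` with ``n_k`` a vector of
  independent Bernoulli(p) bit flips, ``0 < p < 0.5``;
* observation (Gaussian family): ``Y_k = lambda + D X_k + v_k`` with
  ``v_k ~ N(0, sigma^2 I)``, where ``lambda`` holds per-gene baseline
  expression and ``D = diag(delta)`` the differential expression of the ON
  state.  Poisson and negative-binomial observation families with the same
  per-gene means are supported for the particle engine.

For small networks the chain's ``2^n x 2^n`` transition matrix and the
diagonal of per-state observation densities (the update matrix) can be
materialized explicitly; a guard refuses to allocate them beyond
``MATRIX_GUARD`` genes, which is the regime the particle engine exists for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .network import BooleanNetwork, all_states, pack_states, unpack_states

__all__ = [
    "MATRIX_GUARD",
    "CapabilityError",
    "PobdsModel",
    "BeliefVector",
    "Trajectory",
    "step_state",
    "sample_observation",
    "log_obs_density",
    "simulate_trajectory",
    "simulate_trajectories",
    "transition_matrix",
    "update_diagonal",
    "steady_state",
    "sample_steady_states",
    "cache_steady_state_pool",
    "read_trajectory_csv",
    "write_trajectory_csv",
]

#: largest n for which 2^n-sized structures may be materialized by default
MATRIX_GUARD = 14

NOISE_FAMILIES = ("gaussian", "poisson", "negative_binomial")


class CapabilityError(RuntimeError):
    """An exact/matrix operation was requested beyond its feasible size."""


def _guard(n: int, what: str, allow_large: bool) -> None:
    if n > MATRIX_GUARD and not allow_large:
        raise CapabilityError(
            f"{what} requires materializing 2^{n} states (n={n} > guard "
            f"{MATRIX_GUARD}); use the particle engine, or pass "
            f"allow_large=True at your own risk"
        )


@dataclass(eq=False)
class PobdsModel:
    """A Boolean network plus transition-noise and observation parameters."""

    net: BooleanNetwork
    p: float
    lam: np.ndarray
    delta: np.ndarray
    sigma: float = 0.0
    noise_family: str = "gaussian"

    def __post_init__(self):
        n = self.net.n
        self.lam = np.broadcast_to(np.asarray(self.lam, dtype=float), (n,)).copy()
        self.delta = np.broadcast_to(np.asarray(self.delta, dtype=float), (n,)).copy()
        if not 0.0 < self.p < 0.5:
            raise ValueError(f"perturbation probability p={self.p} must lie in (0, 0.5)")
        if self.noise_family not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {self.noise_family!r}")
        if self.noise_family != "poisson" and not self.sigma > 0:
            raise ValueError("sigma must be positive for gaussian/negative_binomial noise")
        if self.noise_family == "negative_binomial":
            max_mean = float(np.max(self.lam + self.delta))
            if self.sigma**2 <= max_mean:
                raise ValueError(
                    "negative_binomial requires overdispersion: sigma^2 "
                    f"({self.sigma ** 2:g}) must exceed every mean "
                    f"(max lambda+delta = {max_mean:g})"
                )
        self._cache: dict = {}

    @property
    def n(self) -> int:
        return self.net.n


@dataclass
class BeliefVector:
    """A probability vector over the ``2^n`` network states."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or self.probs.shape[0] & (self.probs.shape[0] - 1):
            raise ValueError("belief must be a length-2^n vector")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-10:
            raise ValueError("belief entries must be nonnegative and sum to 1")

    @property
    def n(self) -> int:
        return int(self.probs.shape[0]).bit_length() - 1


@dataclass
class Trajectory:
    """An observed expression trajectory, optionally with its latent states."""

    y: np.ndarray  # (T, n) float observations
    x: Optional[np.ndarray] = None  # (T, n) bool latent states, if known
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.x is not None:
            self.x = np.atleast_2d(np.asarray(self.x)).astype(bool)
            if self.x.shape != self.y.shape:
                raise ValueError("latent states and observations must share a shape")

    @property
    def T(self) -> int:
        return self.y.shape[0]

    @property
    def n(self) -> int:
        return self.y.shape[1]


# --------------------------------------------------------------------------
# generative sampling

def step_state(model: PobdsModel, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One stochastic transition ``f(x) XOR Bernoulli(p)`` (vectorized over
    any leading batch dimensions of ``x``)."""
    fx = model.net.evaluate(x)
    flips = rng.random(fx.shape) < model.p
    return fx ^ flips


def _obs_mean(model: PobdsModel, x: np.ndarray) -> np.ndarray:
    return model.lam + model.delta * np.asarray(x, dtype=float)


def sample_observation(model: PobdsModel, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one expression measurement for state ``x`` (batched like ``x``)."""
    mean = _obs_mean(model, x)
    if model.noise_family == "gaussian":
        return mean + model.sigma * rng.standard_normal(mean.shape)
    if model.noise_family == "poisson":
        return rng.poisson(mean).astype(float)
    # negative binomial, moment-matched: mean m, variance sigma^2 > m
    var = model.sigma**2
    r = mean**2 / (var - mean)
    prob = r / (r + mean)
    return rng.negative_binomial(r, prob).astype(float)


def log_obs_density(model: PobdsModel, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Log observation density ``log p(y | x)`` summed over genes.

    ``y`` and ``x`` broadcast against each other on their leading axes; the
    trailing axis is the gene axis and is reduced.
    """
    y = np.asarray(y, dtype=float)
    mean = _obs_mean(model, x)
    if model.noise_family == "gaussian":
        s2 = model.sigma**2
        ll = -0.5 * (y - mean) ** 2 / s2 - 0.5 * np.log(2 * np.pi * s2)
    elif model.noise_family == "poisson":
        ll = y * np.log(mean) - mean - gammaln(y + 1.0)
    else:
        var = model.sigma**2
        r = mean**2 / (var - mean)
        ll = (
            gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * np.log(r / (r + mean)) + y * np.log(mean / (r + mean))
        )
    return ll.sum(axis=-1)


def simulate_trajectory(
    model: PobdsModel,
    T: int,
    rng: np.random.Generator,
    x0: Optional[np.ndarray] = None,
    meta: Optional[dict] = None,
) -> Trajectory:
    """Simulate a length-``T`` trajectory.

    The initial latent state (at time 0, before the first recorded
    observation) is ``x0`` if given, otherwise a draw from the steady-state
    distribution of the perturbed chain.
    """
    Y, X = simulate_trajectories(model, 1, T, rng, x0=None if x0 is None else np.atleast_2d(x0))
    return Trajectory(Y[0], X[0], dict(meta or {}))


def simulate_trajectories(
    model: PobdsModel,
    R: int,
    T: int,
    rng: np.random.Generator,
    x0: Optional[np.ndarray] = None,
    unit_noise: Optional[np.ndarray] = None,
):
    """Simulate ``R`` independent trajectories at once.

    Returns ``(Y, X)`` with shapes ``(R, T, n)``.  ``unit_noise`` may supply
    pre-drawn standard-normal observation noise (Gaussian family only), which
    lets callers pair simulations across different ``sigma`` values.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    n = model.n
    x = sample_steady_states(model, R, rng) if x0 is None else np.broadcast_to(x0, (R, n)).copy()
    X = np.empty((R, T, n), dtype=bool)
    for k in range(T):
        x = step_state(model, x, rng)
        X[:, k] = x
    if unit_noise is not None:
        if model.noise_family != "gaussian":
            raise ValueError("unit_noise pairing only applies to gaussian observations")
        Y = _obs_mean(model, X) + model.sigma * np.asarray(unit_noise, dtype=float)
    else:
        Y = sample_observation(model, X, rng)
    return Y, X


# --------------------------------------------------------------------------
# exact matrix machinery

def transition_matrix(model: PobdsModel, allow_large: bool = False) -> np.ndarray:
    """The ``2^n x 2^n`` column-stochastic transition matrix.

    Entry ``(i, j)`` is ``p^d (1-p)^(n-d)`` with ``d`` the Hamming distance
    between ``f(x^j)`` and ``x^i``.  Cached on the model.
    """
    key = "transition_matrix"
    if key in model._cache:
        return model._cache[key]
    n = model.n
    _guard(n, "transition_matrix", allow_large)
    states = all_states(n)
    fidx = pack_states(model.net.evaluate(states))  # (2^n,)
    d = np.bitwise_count(np.arange(1 << n, dtype=np.int64)[:, None] ^ fidx[None, :])
    M = model.p**d * (1.0 - model.p) ** (n - d)
    model._cache[key] = M
    return M


def update_diagonal(model: PobdsModel, y: np.ndarray, allow_large: bool = False) -> np.ndarray:
    """Diagonal of the update matrix: ``p(y | X = x^i)`` for every state.

    Exact-engine companion of :func:`transition_matrix`; Gaussian family only.
    """
    if model.noise_family != "gaussian":
        raise CapabilityError(
            "the exact update matrix is defined for the gaussian observation "
            "family; use the particle engine for poisson/negative_binomial"
        )
    n = model.n
    _guard(n, "update_diagonal", allow_large)
    y = np.asarray(y, dtype=float)
    if y.shape != (n,):
        raise ValueError(f"observation must have length {n}")
    states = model._cache.setdefault("all_states", all_states(n))
    return np.exp(log_obs_density(model, y, states))


def steady_state(
    model: PobdsModel,
    method: str = "exact",
    rng: Optional[np.random.Generator] = None,
    *,
    tol: float = 1e-12,
    max_iters: int = 1_000_000,
    n_samples: int = 100_000,
    burn_in: Optional[int] = None,
    n_chains: int = 64,
    allow_large: bool = False,
) -> BeliefVector:
    """The stationary distribution of the perturbed Boolean Markov chain.

    ``method="exact"`` runs power iteration on the explicit transition matrix
    to an L1 tolerance of ``tol`` (the chain has strictly positive entries for
    ``0 < p < 0.5``, so the stationary vector is unique and power iteration
    converges).  ``method="monte_carlo"`` returns empirical state-visit
    frequencies from ``n_chains`` parallel chains after ``burn_in`` steps
    (default ``10 * n``).  Both require ``n <= MATRIX_GUARD`` to materialize
    the ``2^n`` vector; for larger networks use :func:`sample_steady_states`,
    which only ever returns draws.
    """
    n = model.n
    _guard(n, "steady_state", allow_large)
    if method == "exact":
        key = "steady_state_exact"
        if key in model._cache:
            return model._cache[key]
        M = transition_matrix(model, allow_large=allow_large)
        S = 1 << n
        if S <= 2048:
            # direct stationary solve: (I - M) pi = 0 with sum(pi) = 1.  Robust
            # even for p -> 0, where the spectral gap vanishes and fixed-point
            # iteration stalls.
            A = np.eye(S) - M
            A[-1, :] = 1.0
            b = np.zeros(S)
            b[-1] = 1.0
            pi = np.linalg.solve(A, b)
            pi = np.clip(pi, 0.0, None)
        else:
            # power iteration; converges geometrically at rate 1 - 2p roughly,
            # adequate for the moderate p of realistic perturbation noise
            pi = np.full(S, 1.0 / S)
            for _ in range(max_iters):
                new = M @ pi
                new /= new.sum()
                if np.abs(new - pi).sum() < tol:
                    pi = new
                    break
                pi = new
            else:
                raise RuntimeError(
                    f"power iteration did not converge within {max_iters} "
                    f"iterations (residual {np.abs(M @ pi - pi).sum():.3e})"
                )
        out = BeliefVector(pi / pi.sum())
        model._cache[key] = out
        return out
    if method == "monte_carlo":
        if rng is None:
            raise ValueError("monte_carlo steady state requires an rng")
        if burn_in is None:
            burn_in = 10 * n
        steps = max(1, n_samples // n_chains)
        x = rng.random((n_chains, n)) < 0.5
        for _ in range(burn_in):
            x = step_state(model, x, rng)
        counts = np.zeros(1 << n)
        for _ in range(steps):
            x = step_state(model, x, rng)
            np.add.at(counts, pack_states(x), 1.0)
        return BeliefVector(counts / counts.sum())
    raise ValueError(f"unknown method {method!r}")


def sample_steady_states(
    model: PobdsModel,
    size: int,
    rng: np.random.Generator,
    burn_in: Optional[int] = None,
    method: str = "auto",
) -> np.ndarray:
    """Draw ``size`` states approximately distributed as the steady state.

    For ``n <= MATRIX_GUARD`` (and ``method != "monte_carlo"``) this draws
    exactly from the cached stationary vector.  Otherwise it runs ``size``
    independent chains from uniform-random starts for ``burn_in`` steps
    (default ``10 * n``) and returns their endpoints — no ``2^n``-sized object
    is ever allocated.  If a draw pool has been installed with
    :func:`cache_steady_state_pool`, draws are resampled from it instead,
    which amortizes the burn-in across the many filter runs of an experiment.
    """
    n = model.n
    if method not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" or (method == "auto" and n <= MATRIX_GUARD):
        pi = steady_state(model, "exact").probs
        idx = rng.choice(pi.shape[0], size=size, p=pi)
        return unpack_states(idx, n)
    pool = model._cache.get("ss_pool")
    if pool is not None:
        return pool[rng.integers(0, pool.shape[0], size=size)]
    if burn_in is None:
        burn_in = 10 * n
    x = rng.random((size, n)) < 0.5
    for _ in range(burn_in):
        x = step_state(model, x, rng)
    return x


def cache_steady_state_pool(
    model: PobdsModel,
    size: int,
    rng: np.random.Generator,
    burn_in: Optional[int] = None,
) -> np.ndarray:
    """Install a reusable pool of Monte-Carlo steady-state draws on a model.

    Subsequent :func:`sample_steady_states` calls on a model whose ``n``
    exceeds the matrix guard resample (with replacement) from this pool
    instead of running fresh burn-in chains.  Idempotent: an existing pool is
    kept.  No effect is needed for small ``n`` where exact draws are used.
    """
    if model.n <= MATRIX_GUARD:
        return model._cache.get("ss_pool", np.empty((0, model.n), dtype=bool))
    if "ss_pool" not in model._cache:
        if burn_in is None:
            burn_in = 10 * model.n
        x = rng.random((size, model.n)) < 0.5
        for _ in range(burn_in):
            x = step_state(model, x, rng)
        model._cache["ss_pool"] = x
    return model._cache["ss_pool"]


# --------------------------------------------------------------------------
# trajectory CSV round trip

def write_trajectory_csv(traj: Trajectory, path, gene_names, states_path=None) -> None:
    """Write observations as ``time,<genes...>`` CSV; latent states optionally
    to a sibling file in the same layout (0/1 entries)."""
    gene_names = list(gene_names)
    df = pd.DataFrame(traj.y, columns=gene_names)
    df.insert(0, "time", np.arange(1, traj.T + 1))
    df.to_csv(path, index=False, float_format="%.17g")
    if states_path is not None:
        if traj.x is None:
            raise ValueError("trajectory has no latent states to write")
        sdf = pd.DataFrame(traj.x.astype(int), columns=gene_names)
        sdf.insert(0, "time", np.arange(1, traj.T + 1))
        sdf.to_csv(states_path, index=False)


def read_trajectory_csv(path, states_path=None, meta: Optional[dict] = None) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "time":
        raise ValueError("trajectory CSV must start with a 'time' column")
    y = df.iloc[:, 1:].to_numpy(dtype=float)
    x = None
    if states_path is not None:
        sdf = pd.read_csv(states_path)
        x = sdf.iloc[:, 1:].to_numpy(dtype=int).astype(bool)
    return Trajectory(y, x, dict(meta or {}, gene_names=list(df.columns[1:])))
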