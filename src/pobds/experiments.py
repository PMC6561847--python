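"""Seeded scenario runner for trajectory-classification experiments.

A :class:`ScenarioConfig` pins down one simulation design: which candidate
networks form the uncertainty class, the POBDS parameters (p, lambda, delta,
sigma, noise family), trajectory length T, training counts D0/D1, particle
count N, engine, test-pool size and replication.  Each replicate regenerates
training data from the *true* (first-listed) healthy and mutated networks,
fits the model posterior, classifies a balanced test pool with the OBC, IBR
and Plug-In rules off a single shared likelihood bank, and records the
misclassification fraction.

Randomness discipline: every stream is derived from the config seed via
``spawn_rng(seed, *key)`` with structured keys ``(replicate, stage, class,
model, ...)``, so identical configs reproduce bit-identical results and
sweeps can share seeds across grid points for paired comparisons.  Sweeps
additionally pair at the data level where possible: the T axis truncates one
set of long trajectories, the D axis nests training sets, the M axis nests
the model class, the N axis reuses the same data, and the sigma axis reuses
latent states and unit observation noise.

For 18-gene networks every steady-state quantity is Monte-Carlo approximated;
a per-model pool of chain draws is precomputed once so particle
initialization stays cheap.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .classify import TrainingSet, UncertaintyClass, multicell_log_density, state_on_marginals
from .engines import make_engine, spawn_rng
from .model import (
    MATRIX_GUARD,
    PobdsModel,
    Trajectory,
    cache_steady_state_pool,
    sample_observation,
    sample_steady_states,
    simulate_trajectories,
)
from .network import BooleanNetwork
from .particle import FilterCollapseError
from .tlgl import tlgl_network

__all__ = [
    "ScenarioConfig",
    "ErrorEstimate",
    "build_uncertainty_class",
    "generate_scenario_data",
    "estimate_error",
    "estimate_errors",
    "estimate_multicell_error",
    "run_comparison_grid",
    "run_sweep",
    "CLASSIFIERS",
]

CLASSIFIERS = ("obc", "ibr", "plugin")

# rng stage tags (spawn-key component after the replicate index)
_STAGE_TRAIN_DATA = 0
_STAGE_TEST_DATA = 1
_STAGE_TRAIN_BANK = 2
_STAGE_TEST_BANK = 3
_STAGE_POOL = 4
_STAGE_MULTICELL = 5
_STAGE_DESIGN_DRAW = 6


@dataclass
class ScenarioConfig:
    """One fully-specified simulation scenario."""

    variants: tuple = ("true", "v2", "v3", "v4")
    p: float = 0.05
    lam: float = 10.0
    delta: float = 30.0
    sigma: float = 20.0
    noise_family: str = "gaussian"
    T: int = 3
    d0: int = 2
    d1: int = 2
    n_test: int = 200  # test trajectories per class per replicate
    n_replicates: int = 50
    engine: str = "apf"
    n_particles: int = 1000
    p0: float = 0.5
    seed: int = 0
    ss_pool: int = 100_000  # Monte-Carlo steady-state pool size (0 = no pool)
    # "fixed_true": data always from the first-listed (true) network pair;
    # "prior_draw": each replicate's generating model per class is drawn from
    # the class prior — the fully-Bayesian evaluation design
    design: str = "fixed_true"
    # optional explicit networks overriding the T-LGL variants; the first
    # network of each class generates the data
    networks0: Optional[Sequence[BooleanNetwork]] = None
    networks1: Optional[Sequence[BooleanNetwork]] = None

    def __post_init__(self):
        self.variants = tuple(self.variants)
        if self.design not in ("fixed_true", "prior_draw"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_replicates < 1 or self.n_test < 1 or self.T < 1:
            raise ValueError("replication, test pool and T must all be >= 1")
        if min(self.d0, self.d1) < 0:
            raise ValueError("training counts must be nonnegative")

    @property
    def M(self) -> int:
        return len(self.networks0) if self.networks0 is not None else len(self.variants)

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if not k.startswith("networks")}
        d["variants"] = list(self.variants)
        if self.networks0 is not None:
            d["networks0"] = [net.rule_text() for net in self.networks0]
            d["networks1"] = [net.rule_text() for net in self.networks1]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        from .network import parse_rules

        for key in ("networks0", "networks1"):
            if raw.get(key) is not None:
                raw[key] = [parse_rules(text) for text in raw[key]]
        return cls(**raw)


@dataclass
class ErrorEstimate:
    """Mean misclassification rate of one classifier under one scenario."""

    classifier: str
    mean: float
    sd: float
    n_replicates: int
    n_failed: int = 0
    config_hash: str = ""

    def __post_init__(self):
        if not 0.0 <= self.mean <= 1.0 or self.sd < 0:
            raise ValueError("error rate must be in [0,1] with nonnegative sd")


# --------------------------------------------------------------------------
# scenario assembly

def _make_model(cfg: ScenarioConfig, net: BooleanNetwork, sigma=None) -> PobdsModel:
    return PobdsModel(
        net=net,
        p=cfg.p,
        lam=cfg.lam,
        delta=cfg.delta,
        sigma=cfg.sigma if sigma is None else sigma,
        noise_family=cfg.noise_family,
    )


def _class_networks(cfg: ScenarioConfig):
    if cfg.networks0 is not None:
        if cfg.networks1 is None or len(cfg.networks0) != len(cfg.networks1):
            raise ValueError("networks0 and networks1 must both be given, same length")
        return list(cfg.networks0), list(cfg.networks1)
    nets0 = [tlgl_network(v, "healthy") for v in cfg.variants]
    nets1 = [tlgl_network(v, "mutated") for v in cfg.variants]
    return nets0, nets1


def build_uncertainty_class(cfg: ScenarioConfig, sigma=None) -> UncertaintyClass:
    """Instantiate the M candidate POBDS models per class with uniform prior."""
    nets0, nets1 = _class_networks(cfg)
    models0 = [_make_model(cfg, net, sigma) for net in nets0]
    models1 = [_make_model(cfg, net, sigma) for net in nets1]
    return UncertaintyClass((models0, models1), p0=cfg.p0)


def _true_models(cfg: ScenarioConfig, sigma=None):
    nets0, nets1 = _class_networks(cfg)
    return _make_model(cfg, nets0[0], sigma), _make_model(cfg, nets1[0], sigma)


def _ensure_pool(cfg: ScenarioConfig, model: PobdsModel, c: int, m: int) -> None:
    """Precompute a Monte-Carlo steady-state pool for a large-n model."""
    if cfg.ss_pool > 0:
        cache_steady_state_pool(model, cfg.ss_pool, spawn_rng(cfg.seed, _STAGE_POOL, c, m))


# --------------------------------------------------------------------------
# data generation

def _simulate_batch(cfg, model, R, T, rng, unit_noise=None):
    return simulate_trajectories(model, R, T, rng, unit_noise=unit_noise)


def _replicate_arrays(cfg: ScenarioConfig, rep: int, *, T=None, d0=None, d1=None,
                      n_test=None, sigma=None, with_unit_noise=False):
    """Generate one replicate's raw arrays.

    Returns ``(trainY, testY, labels)`` with ``trainY = [ (d0,T,n), (d1,T,n) ]``
    and ``testY`` stacking ``n_test`` class-0 then ``n_test`` class-1
    trajectories.  With ``with_unit_noise`` the Gaussian observation noise is
    drawn as standard normal and scaled by sigma, so callers can pair data
    across sigma values by overriding ``sigma``.
    """
    T = cfg.T if T is None else T
    d0 = cfg.d0 if d0 is None else d0
    d1 = cfg.d1 if d1 is None else d1
    n_test = cfg.n_test if n_test is None else n_test
    if cfg.design == "prior_draw":
        uc = build_uncertainty_class(cfg, sigma)
        pick = [
            int(spawn_rng(cfg.seed, rep, _STAGE_DESIGN_DRAW, c).choice(uc.M, p=uc.prior[c]))
            for c in (0, 1)
        ]
        model0, model1 = uc.models[0][pick[0]], uc.models[1][pick[1]]
    else:
        model0, model1 = _true_models(cfg, sigma)
    trainY, testY = [], []
    for c, (model, d) in enumerate(((model0, d0), (model1, d1))):
        rng = spawn_rng(cfg.seed, rep, _STAGE_TRAIN_DATA, c)
        if d:
            noise = rng.standard_normal((d, T, model.n)) if with_unit_noise else None
            Y, _ = _simulate_batch(cfg, model, d, T, rng, unit_noise=noise)
        else:
            Y = np.empty((0, T, model.n))
        trainY.append(Y)
        rng = spawn_rng(cfg.seed, rep, _STAGE_TEST_DATA, c)
        noise = rng.standard_normal((n_test, T, model.n)) if with_unit_noise else None
        Y, _ = _simulate_batch(cfg, model, n_test, T, rng, unit_noise=noise)
        testY.append(Y)
    labels = np.repeat([0, 1], n_test)
    return trainY, np.concatenate(testY, axis=0), labels


def generate_scenario_data(cfg: ScenarioConfig, rep_index: int):
    """One replicate's training set and labeled test trajectories.

    Training/test trajectories come from the true healthy and mutated models
    (the first network of each class); the test pool is balanced.  Fully
    deterministic in ``(cfg.seed, rep_index)``.
    """
    trainY, testY, labels = _replicate_arrays(cfg, rep_index)
    train = TrainingSet((
        [Trajectory(y, meta={"class": 0, "rep": rep_index}) for y in trainY[0]],
        [Trajectory(y, meta={"class": 1, "rep": rep_index}) for y in trainY[1]],
    ))
    tests = [
        (int(lab), Trajectory(y, meta={"class": int(lab), "rep": rep_index}))
        for lab, y in zip(labels, testY)
    ]
    return train, tests


# --------------------------------------------------------------------------
# likelihood banks and decisions

def _bank(cfg, uc, trainY, testY, rep, engine):
    """Log-likelihoods of all trajectories under all (class, model) pairs."""
    M = uc.M
    log_marg = np.zeros((2, M))
    L_test = np.empty((2, M, testY.shape[0]))
    for c in (0, 1):
        for m, model in enumerate(uc.models[c]):
            _ensure_pool(cfg, model, c, m)
            if trainY[c].shape[0]:
                rng = spawn_rng(cfg.seed, rep, _STAGE_TRAIN_BANK, c, m) if engine.stochastic else None
                log_marg[c, m] = engine.loglik_batch(model, trainY[c], rng).sum()
            rng = spawn_rng(cfg.seed, rep, _STAGE_TEST_BANK, c, m) if engine.stochastic else None
            L_test[c, m] = engine.loglik_batch(model, testY, rng)
    return log_marg, L_test


def _decide_bank(uc, log_marg, L_test, classifiers=CLASSIFIERS):
    """Vectorized decisions for every test trajectory from a likelihood bank."""
    with np.errstate(divide="ignore"):
        log_class_prior = np.log(np.array([uc.p0, 1.0 - uc.p0]))
        log_model_prior = np.stack([np.log(uc.prior[c]) for c in (0, 1)])
    out = {}
    for name in classifiers:
        if name == "plugin":
            best = log_marg.argmax(axis=1)
            scores = np.stack([L_test[c, best[c]] for c in (0, 1)])
        else:
            logw = log_model_prior.copy()
            if name == "obc":
                logw = logw + log_marg
            logw = logw - logsumexp(logw, axis=1, keepdims=True)
            scores = logsumexp(L_test + logw[:, :, None], axis=1)
        scores = scores + log_class_prior[:, None]
        out[name] = (scores[0] < scores[1]).astype(int)  # tie -> class 0
    return out


def _replicate_errors(cfg, uc, trainY, testY, labels, rep, engine,
                      classifiers=CLASSIFIERS, model_subset=None):
    log_marg, L_test = _bank(cfg, uc, trainY, testY, rep, engine)
    if model_subset is not None:
        sub = UncertaintyClass(
            (uc.models[0][:model_subset], uc.models[1][:model_subset]), p0=uc.p0
        )
        log_marg, L_test = log_marg[:, :model_subset], L_test[:, :model_subset]
        uc = sub
    decisions = _decide_bank(uc, log_marg, L_test, classifiers)
    return {name: float(np.mean(lab != labels)) for name, lab in decisions.items()}


# --------------------------------------------------------------------------
# public estimators

def _aggregate(cfg, per_rep, n_failed, classifiers):
    chash = cfg.config_hash()
    out = {}
    for name in classifiers:
        vals = np.array([r[name] for r in per_rep])
        out[name] = ErrorEstimate(
            classifier=name,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            n_replicates=len(vals),
            n_failed=n_failed,
            config_hash=chash,
        )
    return out


def estimate_errors(cfg: ScenarioConfig, classifiers=CLASSIFIERS) -> dict:
    """Mean +- sd misclassification of each classifier over the replicates.

    All classifiers are evaluated off one shared likelihood bank per
    replicate (paired by construction).  Replicates in which the particle
    filter collapses are excluded and counted in ``n_failed``.
    """
    engine = make_engine(cfg.engine, cfg.n_particles)
    uc = build_uncertainty_class(cfg)
    per_rep, n_failed = [], 0
    for rep in range(cfg.n_replicates):
        trainY, testY, labels = _replicate_arrays(cfg, rep)
        try:
            per_rep.append(
                _replicate_errors(cfg, uc, trainY, testY, labels, rep, engine, classifiers)
            )
        except FilterCollapseError:
            n_failed += 1
    if not per_rep:
        raise FilterCollapseError(step=0)
    return _aggregate(cfg, per_rep, n_failed, classifiers)


def estimate_error(cfg: ScenarioConfig, classifier: str = "obc") -> ErrorEstimate:
    """Error estimate for a single classifier (see :func:`estimate_errors`)."""
    if classifier not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}")
    return estimate_errors(cfg, (classifier,))[classifier]


def estimate_multicell_error(
    cfg: ScenarioConfig, samples_per_class: Optional[int] = None
) -> ErrorEstimate:
    """Misclassification of the multiple-cell (averaged expression) OBC.

    Training uses ``samples_per_class`` independent steady-state measurements
    per class (default ``T * D_c``, budget-matching the trajectory design's
    total observation count); the test pool matches the trajectory scenario.
    """
    n0 = cfg.T * cfg.d0 if samples_per_class is None else samples_per_class
    n1 = cfg.T * cfg.d1 if samples_per_class is None else samples_per_class
    uc = build_uncertainty_class(cfg)
    model0, model1 = _true_models(cfg)
    # stationary ON-marginals, Monte-Carlo for large n (cached per model)
    for c in (0, 1):
        for m, model in enumerate(uc.models[c]):
            _ensure_pool(cfg, model, c, m)
            state_on_marginals(model, spawn_rng(cfg.seed, _STAGE_MULTICELL, 0, c, m))
    errors = []
    for rep in range(cfg.n_replicates):
        rng = spawn_rng(cfg.seed, rep, _STAGE_MULTICELL, 1)
        Ys, labels = [], []
        train = []
        for c, (model, nc) in enumerate(((model0, n0), (model1, n1))):
            x = sample_steady_states(model, nc + cfg.n_test, rng)
            y = sample_observation(model, x, rng)
            train.append(y[:nc])
            Ys.append(y[nc:])
            labels.append(np.full(cfg.n_test, c))
        Y = np.concatenate(Ys)
        labels = np.concatenate(labels)
        with np.errstate(divide="ignore"):
            log_scores = np.log(np.array([cfg.p0, 1 - cfg.p0]))[:, None] * np.ones((2, Y.shape[0]))
        for c in (0, 1):
            log_marg = np.array(
                [multicell_log_density(mdl, train[c]).sum() for mdl in uc.models[c]]
            )
            with np.errstate(divide="ignore"):
                logw = log_marg + np.log(uc.prior[c])
            logw -= logsumexp(logw)
            Lt = np.stack([multicell_log_density(mdl, Y) for mdl in uc.models[c]])
            log_scores[c] += logsumexp(Lt + logw[:, None], axis=0)
        pred = (log_scores[0] < log_scores[1]).astype(int)
        errors.append(float(np.mean(pred != labels)))
    vals = np.array(errors)
    return ErrorEstimate(
        classifier="multicell_obc",
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        n_replicates=len(vals),
        config_hash=cfg.config_hash(),
    )


# --------------------------------------------------------------------------
# headline experiments

def run_comparison_grid(cfg: Optional[ScenarioConfig] = None, **overrides):
    """High-noise comparison grid: {Plug-In, IBR, OBC} x p in {0.05, 0.1} x
    T in {3, 7} at sigma = 25 with the particle engine.

    Returns ``(DataFrame, results)`` where the frame holds mean errors
    (rows = classifier, columns = (p, T)) and ``results`` maps
    ``(p, T) -> {classifier: ErrorEstimate}``.
    """
    base = cfg if cfg is not None else ScenarioConfig()
    base = replace(base, sigma=25.0, **overrides)
    results = {}
    for p in (0.05, 0.1):
        for T in (3, 7):
            cell = replace(base, p=p, T=T)
            results[(p, T)] = estimate_errors(cell)
    cols = pd.MultiIndex.from_tuples(results.keys(), names=["p", "T"])
    frame = pd.DataFrame(
        {key: {name: est.mean for name, est in ests.items()} for key, ests in results.items()},
        columns=cols,
    ).reindex(["plugin", "ibr", "obc"])
    return frame, results


def run_sweep(axis: str, grid: Sequence, cfg: ScenarioConfig, classifiers=CLASSIFIERS):
    """One error estimate per grid point along ``axis``, paired across points.

    ``axis`` is one of ``T, D, M, N, sigma, noise_family``.  Pairing: shared
    replicate seeds everywhere; additionally the T axis truncates common
    trajectories, D nests training sets, M nests the uncertainty class, N
    reuses the data verbatim, and sigma reuses latent states and unit
    observation noise.  Returns a long-format DataFrame.
    """
    grid = list(grid)
    rows = []

    def record(value, ests):
        for name, est in ests.items():
            rows.append({
                "axis": axis, "value": value, "classifier": name,
                "mean": est.mean, "sd": est.sd,
                "n_replicates": est.n_replicates, "n_failed": est.n_failed,
            })

    if axis in ("T", "D", "M"):
        Tmax = max(grid) if axis == "T" else cfg.T
        dmax = (max(grid) if axis == "D" else cfg.d0 + cfg.d1) // 2
        uc = build_uncertainty_class(cfg)
        engine = make_engine(cfg.engine, cfg.n_particles)
        per_rep = {v: [] for v in grid}
        n_failed = {v: 0 for v in grid}
        for rep in range(cfg.n_replicates):
            trainY, testY, labels = _replicate_arrays(cfg, rep, T=Tmax, d0=dmax, d1=dmax)
            for v in grid:
                tY, sY = trainY, testY
                subset = None
                if axis == "T":
                    tY = [a[:, :v] for a in trainY]
                    sY = testY[:, :v]
                elif axis == "D":
                    tY = [a[: v // 2] for a in trainY]
                elif axis == "M":
                    subset = v
                try:
                    per_rep[v].append(_replicate_errors(
                        cfg, uc, tY, sY, labels, rep, engine, classifiers,
                        model_subset=subset,
                    ))
                except FilterCollapseError:
                    n_failed[v] += 1
        for v in grid:
            record(v, _aggregate(cfg, per_rep[v], n_failed[v], classifiers))
    elif axis == "N":
        for v in grid:
            record(v, estimate_errors(replace(cfg, n_particles=int(v)), classifiers))
    elif axis == "sigma":
        engine = make_engine(cfg.engine, cfg.n_particles)
        for v in grid:
            uc = build_uncertainty_class(cfg, sigma=float(v))
            per_rep, nf = [], 0
            for rep in range(cfg.n_replicates):
                trainY, testY, labels = _replicate_arrays(
                    cfg, rep, sigma=float(v), with_unit_noise=True
                )
                try:
                    per_rep.append(_replicate_errors(
                        cfg, uc, trainY, testY, labels, rep, engine, classifiers
                    ))
                except FilterCollapseError:
                    nf += 1
            record(v, _aggregate(cfg, per_rep, nf, classifiers))
    elif axis == "noise_family":
        for v in grid:
            record(v, estimate_errors(replace(cfg, noise_family=str(v)), classifiers))
    else:
        raise ValueError(f"unknown sweep axis {axis!r}")
    return pd.DataFrame(rows)
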