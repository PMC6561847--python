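# pobds

Simulation and optimal Bayesian classification of gene-regulatory-network
trajectories modeled as **partially-observed Boolean dynamical systems**
(POBDS).

## The problem

Single-cell time-series expression data can, in principle, distinguish a
healthy regulatory program from a diseased one (e.g. a cell in which the
apoptosis pathway can no longer fire).  Two things make this hard: the gene
states are never observed directly — only noisy transcript abundances — and
the regulatory network itself is uncertain, since network inference from
data leaves several plausible wirings.  `pobds` is for computational
biologists who want to classify such trajectories *optimally under that
model uncertainty*, and to study how trajectory length, training size,
uncertainty-class size and measurement noise drive the attainable error.

## The model

The Boolean state `X_k ∈ {0,1}^n` of `n` genes evolves as

    X_k = f(X_{k-1}) ⊕ n_k,          n_k ~ iid Bernoulli(p) per gene,

where `f` is a synchronous Boolean network (one NOT/AND/OR rule per gene)
and `⊕` flips the perturbed bits.  Measurements follow

    Y_k = λ + D X_k + v_k,           v_k ~ N(0, σ² I),

with baseline expression `λ` and differential expression `D = diag(δ)`
(Poisson and negative-binomial channels are also supported by the particle
engine).  Each class `c ∈ {0 = healthy, 1 = mutated}` carries a finite
uncertainty class `Θ = {θ_1..θ_M}` of candidate networks with prior
`π(θ|c)`.  The trajectory log-likelihood under one model,

    L_c^θ(Y_{1:T}) = Σ_k log ‖ T_k(Y_k) M Π_{k-1|k-1} ‖₁,

is computed exactly by the Boolean Kalman filter (transition matrix `M`,
diagonal observation-density update matrix `T_k`) when `2^n` is tractable,
and otherwise by an auxiliary-particle-filter implementation (APF-BKF,
O(NT) per trajectory) whose look-ahead uses the fact that `f(x)` is the
transition mode for `p < 0.5`.  The **optimal Bayesian classifier** decides
class 0 iff

    p⁰ Σ_θ π(θ|𝕐⁰,0) e^{L_0^θ(Y)}  ≥  (1−p⁰) Σ_θ π(θ|𝕐¹,1) e^{L_1^θ(Y)},

with the posterior over models fitted from training trajectories; the IBR
classifier uses the prior instead, and the Plug-In classifier commits to the
per-class maximum-likelihood model.  A multiple-cell variant classifies
steady-state averaged measurements through per-gene two-component Gaussian
mixtures.  The bundled 18-gene T-LGL leukemia survival-signaling network
(healthy, plus a mutated form with Apoptosis frozen OFF, in four regulatory
variants) is the flagship scenario.

## Worked example

```python
import numpy as np
from pobds import (PobdsModel, parse_rules, simulate_trajectory,
                   exact_log_likelihood, apf_log_likelihood,
                   UncertaintyClass, TrainingSet, ExactEngine,
                   fit_posterior, obc_classify)

rules = """
WNT5A   = NOT ERK
ERK     = WNT5A OR ERK
CYCLIN  = ERK AND NOT P53
P53     = NOT CYCLIN
"""
net = parse_rules(rules)
healthy = PobdsModel(net, p=0.05, lam=10.0, delta=30.0, sigma=20.0)
mutated = PobdsModel(net.with_frozen({"P53": 0}), p=0.05,
                     lam=10.0, delta=30.0, sigma=20.0)

rng = np.random.default_rng(7)
traj = simulate_trajectory(mutated, T=6, rng=rng)

ll_h, _ = exact_log_likelihood(healthy, traj)
ll_m, _ = exact_log_likelihood(mutated, traj)
print(f"log-likelihood healthy: {ll_h:.3f}")
print(f"log-likelihood mutated: {ll_m:.3f}")
print(f"APF estimate (mutated): "
      f"{apf_log_likelihood(mutated, traj, N=2000, rng=rng):.3f}")

uc = UncertaintyClass(([healthy], [mutated]))
train = TrainingSet(([simulate_trajectory(healthy, 6, rng) for _ in range(2)],
                     [simulate_trajectory(mutated, 6, rng) for _ in range(2)]))
post = fit_posterior(uc, train, ExactEngine())
decision = obc_classify(uc, post, traj, ExactEngine())
print(f"OBC label: {decision.label}  (log scores: "
      f"{decision.log_scores[0]:.2f} vs {decision.log_scores[1]:.2f})")
```

prints

```
log-likelihood healthy: -110.169
log-likelihood mutated: -108.304
APF estimate (mutated): -108.410
OBC label: 1  (log scores: -110.86 vs -109.00)
```

The trajectory was simulated from the mutated model (P53 frozen OFF); its
exact log-likelihood is ~1.9 nats higher under the mutated model, the
2000-particle APF estimate agrees with the exact value to ~0.1 nats, and the
OBC assigns label 1 because the class-1 posterior-weighted log score (−109.0)
beats the class-0 score (−110.9).

## Scenario experiments and CLI

`pobds.experiments.ScenarioConfig` pins a full simulation design (networks,
`p, λ, δ, σ`, `T`, training counts, particle count, replication, seed);
`estimate_errors` returns mean ± sd misclassification for OBC/IBR/Plug-In
off one shared likelihood bank, `run_comparison_grid` executes the high-noise
comparison grid, and `run_sweep` produces paired-seed error curves along
`T`, `D`, `M`, `N`, `σ` or the noise family.  The same functionality is
scriptable from the shell:

```sh
pobds simulate --config scenario.yaml --out data/
pobds classify --config scenario.yaml --train-dir data/ \
      --test data/test/traj_0000.csv --out decisions.json
pobds compare-grid --seed 1 --reps 10 --out results/
pobds sweep --axis T --grid 2,3,5,7 --seed 1 --out results/
```

See `docs/methods.md` for the model assumptions, numerical choices and the
two supported data-generation designs.

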