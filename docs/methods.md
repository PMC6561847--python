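# Methods

## Model

`pobds` simulates gene regulatory networks as partially-observed Boolean
dynamical systems (POBDS).  The latent state `X_k ∈ {0,1}^n` holds the
ON/OFF status of `n` genes and evolves as

    X_k = f(X_{k-1}) ⊕ n_k,

where `f` is the synchronous Boolean network function (one update rule per
gene over NOT/AND/OR) and `n_k` has independent Bernoulli(p) components —
each gene's deterministic update is flipped with probability `p`.  The model
requires `0 < p < 0.5`: perturbation makes the chain irreducible and
aperiodic (every transition probability `p^d (1-p)^{n-d}` is positive), so a
unique stationary distribution `π^∞` exists, and `p < 0.5` makes the
noise-free update `f(x)` the mode of the transition density — the property
the auxiliary particle filter's look-ahead exploits.

Expression measurements follow the Gaussian linear channel

    Y_k = λ + D X_k + v_k,   v_k ~ N(0, σ² I),

with `λ_j` the baseline (OFF) expression of gene `j` and `δ_j = D_jj` its
differential expression when ON.  Poisson (mean `λ_j + δ_j x_j`) and
moment-matched negative-binomial (same mean, variance `σ²`, requiring
`σ² > mean`) channels are available for the particle engine; the NB shape is
`r = m²/(σ² − m)`, the unique NB with that mean/variance pair.

A *mutation* is modeled as a frozen gene: its output ignores the regulating
rule and is pinned to a constant (perturbation noise can still flip it, as
the noise applies after the update).  The bundled T-LGL leukemia network
(18 genes) uses this to define the cancerous class: Apoptosis stuck at OFF.

## Trajectory likelihood

Exact engine (`pobds.exact`).  The Boolean Kalman filter propagates the full
belief vector over `2^n` states with the transition matrix
`M_ij = p^{H(f(x^j), x^i)} (1-p)^{n-H}` (`H` = Hamming distance) and the
diagonal update matrix of per-state Gaussian densities.  The trajectory
log-likelihood is the sum of the per-step log L1-normalizers.  We run the
scaled form (renormalizing the belief each step), which is algebraically
identical to the product of unnormalized norms but immune to underflow for
long horizons.  The filter prior is the chain's stationary vector.  For
`2^n ≤ 2048` the stationary vector is obtained by a direct linear solve of
`(I − M)π = 0` with a normalization row — robust even as `p → 0`, where the
spectral gap vanishes; for larger state spaces power iteration (L1 tolerance
1e-12) is used, which converges quickly at realistic `p`.  An enumeration
oracle (`brute_force_log_likelihood`, explicit sum over all latent state
sequences, bounded to `nT ≤ 20`) validates the recursion in the tests to
1e-9.

All `2^n`-sized objects are refused above `MATRIX_GUARD = 14` genes
(2^28-entry matrices): the failure is explicit and points to the particle
engine rather than exhausting memory.

Particle engine (`pobds.particle`).  The auxiliary-particle-filter
implementation of the BKF (APF-BKF) keeps `N` Boolean particles.  Per step:
first-stage weights `v_i = p(y | f(x_i)) w_{i}` (the look-ahead evaluates
each particle's propagation *mode*), categorical ancestor draw from `v`
(multinomial by default, matching the categorical sampling the method
defines; systematic resampling is an opt-in variance reduction), Bernoulli
propagation of the selected modes, second-stage ratio weights
`w'_j = p(y|x'_j)/p(y|f(x_{ζ_j}))`, and the likelihood increment
`log[(mean v)(mean w')]`.  Weights are renormalized to mean 1 between steps,
which makes the product of per-step increments a consistent (and, in linear
space, unbiased) likelihood estimate; the tests verify the mean of
`exp(estimate)` against the exact likelihood.  All weight arithmetic is in
log space with max-subtraction — linear-space Gaussian likelihoods at
`n = 18, σ = 20` underflow.  If every first-stage weight is zero even in log
space the filter raises a collapse error naming the time step; with the
Gaussian/Poisson/NB channels the density is strictly positive, so this
signals a configuration pathology rather than an expected event.  Cost is
O(NTn) time and O(Nn) memory; an 18-gene trajectory with `N = 1000` runs
without allocating any `2^18`-sized structure.  A plain bootstrap (SIR)
filter is included as the no-look-ahead baseline.

Steady-state draws for particle initialization and data generation come from
the exact stationary vector when `n ≤ 14`, otherwise from endpoints of
independent Monte-Carlo chains burnt in for `10n` steps from uniform random
starts.  Because an experiment runs thousands of filters per model,
`cache_steady_state_pool` precomputes a pool (default 100 000 draws) per
model once and later initializations resample from it; the approximation this
introduces is the same Monte-Carlo approximation already inherent in the
draws, and the pool is keyed to a dedicated seed stream so runs stay
bit-reproducible.

## Classification under model uncertainty

Each class `c ∈ {healthy, mutated}` carries a finite uncertainty class of
`M` candidate network functions with prior `π(θ|c)` (uniform by default —
the simulation designs are symmetric and no informative prior is stated) and
class prior `p⁰ = 0.5`.  Given training trajectories, the model posterior is
`π(θ|𝕐^c, c) ∝ exp(Σ_d L_c^θ(𝒴^{(d)})) π(θ|c)`, computed with log-sum-exp.
Three rules share one likelihood bank:

* **OBC**: class score `p_c · Σ_θ π(θ|𝕐^c,c) exp(L_c^θ(Y))` — the
  posterior-expected class-conditional density;
* **IBR**: the same with the prior in place of the posterior (ignores
  training data);
* **Plug-In**: the Bayes rule at the per-class maximum-marginal-likelihood
  model (ties → lowest model index).

Score ties resolve to class 0 (the decision rule uses ≥).  With `M = 1` all
three reduce to the same likelihood-ratio rule, and with no training data
the posterior degrades to the prior, making OBC ≡ IBR.

Multiple-cell (averaged expression) classification uses the stationary
mixture: each gene's measurement is
`(1−q_j) N(λ_j, σ²) + q_j N(λ_j+δ_j, σ²)` with `q_j` the gene's stationary
ON-marginal (exact for `n ≤ 14`, Monte-Carlo otherwise).  Training samples
are independent steady-state draws pushed through the observation channel,
matching the mixture's independence assumption.

## Simulation designs

`ScenarioConfig` pins one experiment.  Defaults mirror the study conditions:
the T-LGL uncertainty class `{true, v2, v3, v4}` × {healthy, mutated},
`λ = 10`, `δ = 30` for every gene, `σ ∈ {20, 25}` (low/high observation
noise), `p ∈ {0.05, 0.1}`, `D = D_0 + D_1 = 4` training trajectories split
evenly (the design is symmetric everywhere else), `N = 1000` particles,
balanced test pools.  Variant `v2` drops the `¬Apoptosis` factor from the
sFas and GPCR rules, `v3` from the IAP and P2 rules, and `v4` swaps the
connective inside the BID rule's negation (`¬(MCL1 ∨ Apoptosis)` →
`¬(MCL1 ∧ Apoptosis)`); the BID rule as printed has a single connective, so
the swap is applied to it, and the exact edit is pinned in the fixture file.

Two data-generation designs are provided.  `fixed_true` (default) draws all
training and test trajectories from the first-listed ("true") network pair —
the candidates model uncertainty *about* a fixed ground truth.  `prior_draw`
draws each replicate's generating model per class from the class prior — the
fully-Bayesian evaluation under which the OBC is optimal by construction.
The choice matters for how much the three rules separate: under
`fixed_true` the wrong candidates are likelihood-close to the fixed truth,
so posterior weighting, prior weighting and hard selection behave similarly
on the default class, while under `prior_draw` adapting to the training data
pays and the OBC's advantage over the IBR widens.  In both designs the
penalty of hard model selection (Plug-In) is limited by how wrong the
selectable candidates can be; the acceptance script reports the measured
improvements for the default design.

Replication defaults are 50 replicates × 200 test trajectories per class per
replicate (standard error ≈0.005 on an error rate of 0.15), chosen as a
desk-scale design; the test suite uses smaller pools.  Every random stream
derives from the config seed via `SeedSequence` spawn keys
`(replicate, stage, class, model, …)`, so identical configs are
bit-reproducible and sweeps pair seeds across grid points.  Sweeps
additionally pair data: the T axis truncates one set of long trajectories,
the D axis nests training sets, the M axis nests the model class, the N axis
reuses the data verbatim, and the σ axis reuses latent states and unit
observation noise.  Failed replicates (filter collapse) are excluded and
counted, never silently dropped.

## What the generator does and does not emulate

Synthetic trajectories realize exactly the generative model above:
Markovian Boolean dynamics with homogeneous per-gene flip noise, stationary
initial states, and conditionally independent per-gene observation noise
with shared `λ, δ, σ` across genes.  Real single-cell data violate several
of these (cell-cycle and lineage structure, gene-specific baselines and
dispersions, dropout/zero inflation, asynchronous updates); passing tests
therefore certify the inference and classification machinery under the
model's assumptions, not robustness to those violations.  Dropout models and
per-gene perturbation rates are out of scope.

## Numerical choices

* Transition matrices are validated column-stochastic to 1e-12; beliefs and
  posteriors normalized to 1e-10; stationary residual `‖Mπ−π‖₁ < 1e-10`.
* Update densities, mixture densities and all classifier scores are handled
  in log space end to end.
* The BKF raises rather than returning `-inf` if a normalizer underflows to
  zero in linear space (only reachable with pathological σ).
* The enumeration oracle is limited to `nT ≤ 20`; the exact engine to
  `n ≤ 14`; both failures are explicit capability errors.
* Plug-In model-selection ties break to the lowest index and decision ties
  to class 0, so every stochastic path is reproducible bit for bit under a
  fixed seed.

## Known limitations

* The exact engine supports only the Gaussian channel (the update matrix is
  defined by the Gaussian density); Poisson/NB run through the particle
  engine only.
* Under the `fixed_true` design with particle likelihoods, averaging scores
  over the model mixture also averages out filter noise; prior/posterior
  mixtures (IBR/OBC) therefore tie or slightly beat hard selection even when
  selection is nearly always right, and growing the training set — which
  concentrates the posterior — does not necessarily reduce the OBC's error
  there.  The training-size benefit shows cleanly in the Plug-In rule and in
  the `prior_draw` design.
* Monte-Carlo stationary pools trade a small, shared initialization error
  for large speedups; pool draws are only approximately independent.
* The multiple-cell model treats each averaged measurement as one draw of
  the stationary mixture with variance σ², with no explicit averaging count.
* Smoothing, parameter learning inside the filter, intervention/control and
  network-structure inference are out of scope.
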