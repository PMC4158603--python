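# Methods

## Model and objective

The package solves box-bounded inverse problems for ODE kinetic models.
A candidate parameter vector θ is scored by the discretized weighted
least-squares cost

    J(θ) = Σ_experiments Σ_times Σ_observed  w_ij · (y_pred(θ) − y_obs)²

with predictions from a classic fixed-step fourth-order Runge–Kutta solve.
Only bound constraints are supported; general path/point constraints are
out of scope. Two weighting schemes exist: unit weights (α-pinene) and
w_ij = (1/max_t |reference|)² per experiment × variable (three-step
pathway). For the latter, the maxima are taken **once** from the noise-free
nominal-model trajectories and frozen. The alternative reading — maxima of
the predicted trajectory at the current θ — would make J a non-separable,
θ-dependent functional whose value at the same θ changes between runs of
different histories; freezing the reference keeps J a fixed, reproducible
function of θ.

A forward solve whose state becomes non-finite (extreme rates or Hill
exponents readily overflow) yields the finite penalty J = 1e12 rather than
an exception, so stochastic optimizers retain a total fitness ordering.

## Forward solver

Fixed-step RK4 with `substeps` equal sub-intervals between consecutive
sample times (and from t = 0 to the first sample); default `substeps = 20`.
The solver is deliberately *not* adaptive: data generation and objective
evaluation share one deterministic discretization, so J(θ_nominal) on
noise-free data is exactly zero and the empirical convergence order (≈ 4)
is testable. With the default grids the α-pinene mass-conservation residual
stays below 1e-6 (in practice ~1e-13). Divergent trajectories are flagged,
not raised. The two builtin models run through numba-compiled kernels
(~10 µs / ~1.5 ms per objective evaluation for case 1/2); the same scheme
in plain Python serves plug-in models and is tested to agree with the
kernels to rounding. Divergence detection lives outside the
fastmath-compiled arithmetic because fastmath licenses the compiler to
assume no NaN/Inf ever occurs.

## Benchmark conditions

* **α-pinene (case 1)**: nominal rates (5.93, 2.96, 2.05, 27.5, 4.00)·1e-5;
  x0 = (100, 0, 0, 0, 0) (pure reactant, concentrations as percentages, the
  conventional starting point for this benchmark — the original description
  leaves x0 open); the classical 8 measurement times 1230 … 36420 min;
  bounds [0, 1e-3]^5; uniform initialization; unit weights.
* **three-step pathway (case 2)**: the 36 nominal values in decision-vector
  order; 16 experiments = {0.1, 0.46416, 2.1544, 10} (S) × {0.05, 0.13572,
  0.3684, 1.0} (P), S-major; x0 = 0.1 for all 8 species and 21 uniform
  samples on [0, 120] time units (both unstated in the source benchmark —
  chosen so every Hill/Michaelis–Menten term is defined at t = 0 and the
  transients plus steady state are sampled; configurable); bounds
  [1e-6, 1e2]^36 with log-uniform initialization (the parameters span
  orders of magnitude and must stay positive); inverse-max-squared weights.
* **Noise**: z' = z + σ·ε, ε ~ N(0,1) i.i.d. per cell, σ = 0.01, one seeded
  generator per dataset in experiment-major/time-major/variable-minor cell
  order.

Because x0 and the sampling grids are package choices, absolute J values on
noisy data (which scale with the number of residuals) are comparable across
implementations only in order of magnitude.

## RDPSO update

Velocity = thermal + drift:

    V = α·|C − X|·φ + β·(p − X),   φ = ±ln(1/u),  u, s ~ U(0,1), sign from s > 0.5
    p = φ'·Pbest + (1 − φ')·G,     φ' ~ U(0,1)

C is the centroid of all personal bests, computed once per iteration before
the particle sweep. Each particle is evaluated, its personal best (strict
improvement) and the global best (argmin over personal bests, ties to the
lowest particle index) updated, and then moved — so later particles in the
same sweep already see earlier improvements. Velocities are clamped
elementwise to ±Vmax (default 0.5·(θU − θL); the benchmark protocol states
no value) and positions clamped to the bounds (out-of-bounds handling is
likewise unstated; clamping is the simplest scheme that preserves
feasibility). Initial velocities are zero. Personal bests start at the
initial positions with +∞ fitness and are scored by the first iteration's
sweep, making eval_count = m × iterations exactly, which is what the
budget-matched comparisons count.

A one-dimensional stability probe (attractor pinned at the origin, mean
best at 0.1, no clamping) separates the bounded regime (e.g. α = 1,
β = 1.5) from the divergent one (α = 1.8, β = 1.5) by orders of magnitude
in max |X_k|; the tests assert this separation.

## Baselines

* **PSO**: V ← wV + c1·r·(P−X) + c2·R·(G−X) with the same sweep ordering,
  clamping and accounting as RDPSO.
* **DE/rand/1/bin**: mutant x_r1 + F·(x_r2 − x_r3) with distinct indices by
  rejection sampling, binomial crossover with one guaranteed mutant
  coordinate, greedy (≤) selection, synchronous generations; the
  initial-population evaluation counts as the first iteration. The
  benchmark names only F and CR, so the canonical rand/1/bin scheme is
  used.
* **ES**: non-adaptive isotropic Gaussian mutation with per-dimension std
  varphi·(θU − θL)/100, parents chosen uniformly, comma or plus selection.
  The benchmark fixes only varphi = 1; no self-adaptation or recombination
  is assumed. eval_count = μ + λ × generations (the μ initial parents are
  scored once).

All optimizers are deterministic functions of (problem, config, seed); the
repeated-run harness gives run r the seed base_seed + r and reports best /
mean / sample standard deviation (n−1 denominator; the benchmark does not
state which estimator it used) of the final J values, plus pointwise-mean
convergence curves.

## Numerical and design notes

* The local attractor is implemented as φ'P + (1−φ')G — the convex
  combination that follows from the PSO attractor decomposition; the
  printed form of the update omits the G factor, which would make p
  dimensionally inconsistent with a position.
* The thermal velocity is taken directly from the final update equation
  (α·|C−X|·φ); the intermediate σ-scaled formulation is typographically
  corrupted in the source and adds nothing once the adaptive scale is
  substituted.
* Exact mass conservation of the α-pinene right-hand side holds
  analytically; in floating point each derivative component is rounded
  separately, so tests assert cancellation at 1e-12 relative, and
  trajectory-level conservation at 1e-6.
* Table-driven parameter order for the three-step pathway lists the G2
  activation constant twice under the same label; position 10 is the
  activation constant Ka2, as required by the G2 equation's structure.
* Desk-scale protocol sizes: the α-pinene experiments use the full
  benchmark budget (20 runs × 500 iterations × population 100). The
  three-step experiments at the full benchmark budget (20 × 2.25M evaluations)
  are tens of CPU-hours; the package's test protocol instead uses 5 runs ×
  2000 iterations × population 40 and checks relative improvement and
  Hill-coefficient recovery rather than absolute full-budget J values.

## What the generator does and does not emulate

Pseudo-data are the model's own output plus homoscedastic Gaussian noise.
Passing tests therefore demonstrate optimizer and objective correctness
under a perfectly specified model — no model mismatch, no heteroscedastic
or multiplicative error, no missing observations, and no unobserved states
(both benchmarks observe every state). Real calibration problems violate
all of these; results here say nothing about robustness to model error.

## Known limitations

* Fixed-step RK4 is not appropriate for stiff regions of parameter space;
  extreme θ are penalized rather than integrated accurately.
* The three-step search space [1e-6, 1e2]^36 includes large regions where
  Hill terms overflow; the penalty makes these flat plateaus that slow
  progress, which is the intended difficulty of the benchmark rather than a
  solver defect.
* Weights, bounds and initialization scheme are frozen per problem at
  construction; schedule-style adaptation of α/β is out of scope.
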