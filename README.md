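# driftfit

Kinetic parameter estimation for nonlinear biochemical ODE models by random
drift particle swarm optimization (RDPSO), with canonical baselines and a
fully reproducible pseudo-experiment benchmark harness.

## The problem

Given time-course measurements `y_msd` of a biochemical system modelled by
ODEs `dx/dt = f(x, θ, v, t)`, `x(t0) = x0`, calibration is the inverse
problem of finding the kinetic parameters θ within box bounds
`θL ≤ θ ≤ θU` that minimize the discretized weighted least-squares cost

    J(θ) = Σ_i Σ_j w_ij · ( y_pred(θ)_ij − y_msd_ij )²

where `y_pred` comes from a fixed-step fourth-order Runge–Kutta solve of the
model at θ. These problems are multimodal and ill-conditioned, so the
package attacks them with stochastic global optimizers.

## The optimizer

RDPSO treats each swarm particle like a free electron in a conductor under
an external field: its velocity superimposes a random **thermal** motion and
a directed **drift** motion,

    V_ij ← α · |C_j − X_ij| · φ_ij  +  β · (p_ij − X_ij),      X_ij ← X_ij + V_ij

with φ ~ Laplace(0, 1) sampled as ±ln(1/u), C the mean of all personal-best
positions, and p_ij = φ'·P_ij + (1−φ')·G_j a random convex combination of
the particle's personal best and the global best (φ' ~ U(0,1)). The
heavy-tailed thermal term, scaled by each particle's distance to the swarm
centroid, supplies occasional long exploratory jumps that shrink
automatically as the swarm converges; the drift term pulls toward the local
attractor. α (thermal coefficient) and β (drift coefficient) balance
exploration against exploitation; defaults are α = 0.75, β = 1.0 with a
population of 100. Baselines sharing the same interface: canonical
gbest-topology PSO (w = 0.729, c1 = c2 = 1.49), DE/rand/1/bin (F = 0.5,
CR = 0.55), and (μ,λ)/(μ+λ) evolution strategies (λ = 100, μ = 10).

## Benchmark systems

* **`alpha_pinene`** — thermal isomerization of α-pinene: 5 states, linear
  first-order network, 5 unknown rate constants (nominal p1 = 5.93e-5 …
  p5 = 4.00e-5), one experiment, unit weights.
* **`three_step`** — a three-step gene/enzyme/metabolite cascade: 8 states,
  Hill-type transcription control plus reversible Michaelis–Menten fluxes,
  36 unknown parameters, 16 experiments over a 4×4 grid of fixed substrate/
  product levels (S, P), inverse-max-squared weights.

"Measurements" are the nominal model's own RK4 output, optionally corrupted
with additive white Gaussian noise (σ = 0.01), so J(θ_true) = 0 exactly in
the noise-free setting — a built-in correctness check.

## Worked example

```python
import driftfit as df

problem = df.build_problem(case=1)              # noise-free alpha-pinene
results = df.run_trials("rdpso", problem, n_runs=5, iters=500, base_seed=0, m=100)
stats = df.summarize(results)
best = min(results, key=lambda r: r.best_J)
print(f"best J = {stats.best_J:.4g}, mean J = {stats.mean_J:.4g}")
print("best rate constants:", best.best_theta)
```

Output from this exact snippet:

```
best J = 0, mean J = 3.941e-30
best rate constants: [5.93e-05 2.96e-05 2.05e-05 2.75e-04 4.00e-05]
```

The best run recovers all five nominal rate constants to machine precision
— because the pseudo-data are the model's own (bit-identical) RK4 output,
the residuals can genuinely reach zero; on real or noisy data J bottoms out
at the noise floor instead.
The same workflow is scriptable from the shell:

```sh
driftfit simulate --case 2 --noise 0.01 --seed 3 --out data.csv
driftfit fit --case 1 --algorithm rdpso --runs 20 --iters 500 --seed 0 --out results.json
driftfit benchmark --config exp.yaml --out-dir out/
```

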