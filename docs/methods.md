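# Methods

## Model

`propgen` describes a haploid asexual population over a finite genotype
set `G` and phenotype set `P`. Fitness is Malthusian and attached to the
phenotype: an individual of phenotype `p` reproduces at rate `X(p)` per
unit time. The genotype–phenotype relationship is probabilistic and acts
at birth: an offspring whose (possibly mutated) genotype is `g`, born to
a parent of phenotype `k`, is assigned phenotype `p` with probability
`φ_g(k→p)`. Because this assignment rides on replication, it is coupled
to both fitness and mutation — the modelling choice that distinguishes
*phenotype noise at birth* from *stochastic phenotype switching* (SPS),
which occurs during an individual's lifetime at rate `S(p)` with targets
`σ_g(k→p)` and is decoupled from reproduction. Genotypes change through
two channels as well: per-replication mutation `μ_{g→h}` (rows sum to 1
including the self-transition, so `μ_{gg} = 1 − Σ_{h≠g} μ_{gh}`) and
spontaneous lifetime mutation at rate `R(p)` with targets `m_{g→h}`
(zero diagonal, rows sum to 1 over `h ≠ g`). After a spontaneous
genotype change the phenotype is re-drawn through `φ` of the new
genotype.

The infinite-population frequency dynamics are the five-term
replicator–mutator equation shown in the README. Each term conserves
total frequency; the implementation evaluates the terms separately
(`propgen.ode.propgen_rhs_terms`) so tests can assert per-process
conservation, and the five terms provably telescope to the compact form

    df_g(p)/dt = Σ_{h,k} X(k) f_h(k) μ_{h→g} φ_g(k→p) − X̄ f_g(p)
                 + (spontaneous) + (SPS),

which is the route used for the exact equilibria below. Genetic drift is
not integrated as a noise term; finite-`N` stochasticity enters only
through the agent-based simulator.

Edge conventions: with a single phenotype (`P = 1`) the off-diagonal
switching simplex is empty, so `σ` is all-zero and `S` must be zero
(likewise `m`/`R` for `G = 1`). Builders for multi-state models emit
uniform off-diagonal `σ`/`m` rows alongside zero rates so that validation
is strict for every active process.

## ProSeD simulator

One dilution cycle of duration `dt`:

1. each individual of phenotype `p` spawns one offspring with probability
   `dt·X(p)`; parents persist (overlapping generations);
2. offspring genotype ~ `μ[g, ·]`, then phenotype ~ `φ[h, k, ·]`;
3. spontaneous mutation with probability `dt·R(p)` per individual, new
   genotype ~ `m[g, ·]`, phenotype re-drawn through `φ`;
4. SPS with probability `dt·S(p)`, target ~ `σ[g, k, ·]`;
5. dilution to exactly `N` individuals by multivariate-hypergeometric
   sampling (uniform, without replacement) — the analogue of pipetting
   an aliquot into fresh broth.

The within-step order (reproduce → spontaneous → SPS → dilute) is fixed
for reproducibility; all per-event probabilities are O(dt), so the order
is immaterial in the limit the continuum theory describes. Randomness
comes from counter-based Philox streams; trial `k` of a run uses
`SeedSequence(base_seed, spawn_key=(k,))`, so trials are independent and
individually reproducible, and identical seeds give bitwise-identical
trajectories.

**Discreteness.** The expected per-cycle update is exactly
`n → (I + dt·B) n` for the birth operator `B`, so the simulator's
relaxation rates are log-compressed relative to the continuum:
`[ln(1 + dt λ_i) − ln(1 + dt λ_j)]/dt` instead of `λ_i − λ_j`. At
per-step reproduction probability `r = dt·X` the relative rate bias is
≈ `dt(λ_i + λ_j)/2` ≈ `r`. Consequences drawn in this package:

- Continuum-tracking assertions (ensemble mean vs ODE within 3×SE) are
  made at `r ≤ 0.02`.
- The serial-dilution count for buoy equilibration uses `dt = 1`
  (`r = 0.1`), where ensembles settle inside the 0.02 band within ≈200
  dilutions.
- For bridge time constants, `propgen.bridge.tau_discrete` gives the
  exact time constant of the expected discrete dynamics (it converges to
  the continuum `tau_theory` as `dt → 0`); simulator estimates are
  compared against it with jackknife-over-trials confidence intervals,
  and against the continuum value within a 10% band at `r = 0.05`.

## Exact results and their oracles

Every closed form ships with an independent numeric route and is only
trusted where the two agree:

- **2×2 equilibrium.** With parent-independent noise the equilibrium
  factorizes as `f_g(p) = F_g φ_g(p)`; the genotype masses solve a 2×2
  eigenproblem whose characteristic root gives `X̄_eq`, and the
  eigenvector is taken in the subtraction-safe form
  `(μα_1, X̄_eq − (1−μ)α_0)`. Oracles: the Perron eigenvector of the full
  4×4 birth matrix, the numeric fixed point of the general rhs, and
  long-time integration — all agree to better than 1e-8 relative over
  10³ random parameter draws. At `μ = 0` the spectrum degenerates and the
  closed form returns the pure dominant-genotype limit explicitly.
- **Phase diagrams.** Orderings of the four pair frequencies on an open
  `(π_1, μ)` lattice (endpoints offset by half a cell), ties flagged at
  relative tolerance 1e-9 and excluded from sector counts. At
  `π_0 ∈ {0.4, 0.6}` (fit:unfit fitness 2:1 default, robust across
  ratios 1.5–4) exactly 11 sectors appear; a fixed `π_0 ≠ 0.5` pins the
  within-genotype-0 order, halving the 24 permutations to at most 12.
  Boundary curves solve `f_i = f_j` by bracketed root-finding scanned in
  both axis directions (curves can run nearly vertically). Exact
  symmetry used in tests: genotype exchange,
  `feq(π_0, π_1) = block-swap of feq(π_1, π_0)`.
- **Bridge time constant.** Linearizing the four-node valley system, the
  slow mode is the antisymmetric start↔end genotype mode with decay rate
  `X(0)·(λ_top − (1−μ))`, giving the closed form in the README; for small
  `μ`, `τ ≈ (1−θ)/(θ μ²)`. Oracle: central-difference Jacobian at the
  exact equilibrium, projected onto the simplex tangent space; agreement
  to 1e-6 relative over a 10³-point `(π, γ, μ)` lattice. Limits forced
  by the algebra: `τ(μ=0) = ∞` (handled exactly, not by floating-point
  cancellation) and `τ(γ=1) = 1/μ`.
- **Empirical τ.** The estimator fits `f_e(t) = f_eq(1 − A e^{−t/τ})`
  with the asymptote pinned to the exact equilibrium, a free slow-mode
  amplitude `A`, and the first 10% of the record discarded. The free
  amplitude is the form the linearization actually predicts once fast
  modes decay; fixing `A = 1` and fitting from `t = 0` biases τ upward
  by up to 8% at large `π` (fast-mode contamination), which the
  diagnostics exposed, so that variant is available but not the default.
  On deterministic trajectories over a 3τ window the default estimator
  recovers τ to < 0.1%.
- **Persister closed form.** Dormant cells wake at `S(t) = α e^{βt}`;
  damaged cells convert to healthy through birth noise `φ_DH` riding on
  replication. The exact solution uses differences of the lower
  incomplete gamma function `γ(q, c e^{βt}) − γ(q, c)`, which remain
  finite for any real `q` since `c = α/β > 0`; for `q ≤ 0` they are
  computed by adaptive quadrature of the monotone integrand (capped where
  it underflows), for `q > 0` through the regularized scipy routine, the
  two cross-checked where both apply. The removable singularity
  `X_H = X_D(1−φ_DH)` is evaluated through the resonant
  variation-of-parameters integral, not by perturbing parameters.
  Oracle: adaptive integration of the rhs, max relative error < 1e-6
  over 100 random parameterizations.

## Reference scenarios and defaults

Parameters not fixed by the model definitions were chosen once and are
recorded as "defaulted" in scenario metadata:

| scenario | parameters | sizes |
|---|---|---|
| buoy / phase | `π_0 = 0.4` (phase also 0.5, 0.6), `1−π_1 ∈ {0.5…0.1}`, `X = (0.1, 0.05)`, `μ = 0.05` | `N = 10⁴`, `dt = 1`, 10 trials, 250 dilutions |
| bridge | `γ = 0.5`, `μ = 0.1`, `π ∈ {0, 0.05, 0.1, 0.15, 0.4}`, `X(0) = 1` | `N = 10⁴`, `dt = 0.05`, 100 trials, 3τ horizon |
| absolute fitness | `X = (0.1, 0.05)`, shift `A = 0.1`, probabilistic map `π = (0.8, 0.2)` | `N = 10⁴`, `dt·max(X+A) = 0.01`, 50 trials |
| mean-fitness decrease | `X = (0.09, 0.02)`, `φ_0(0) = 0.1`, `φ_1(0) = 0.8`, `μ = 0`, start `(0.4, 0.1, 0.05, 0.45)` | ODE, 500 time units |
| persister | `α = 1`, `β = 0.5`, `σ = (0.2, 0.3, 0.5)`, `X_D = 0.3`, `X_H = 1`, `φ_DH = 0.4`, start all-dormant | closed form + ODE, `t ∈ [0, 10]` |

The fitness pair (0.1, 0.05) keeps per-step reproduction probabilities
well below 1 at `dt = 1` while giving a 2:1 selective contrast; `μ` for
the bridge sweep controls the equilibration scale (`τ ~ μ⁻²`) and 0.1
puts all five sweep members at desk scale; the persister values are
chosen to reproduce the qualitative resuscitation phenomenology
(transient damaged/failed peaks, healthy takeover) — empirical fits from
time-lapse experiments are not bundled.

## What the synthetic conditions do and do not show

The scenario catalog and random-model generator exercise exact
mathematical structure (equilibria, spectra, closed forms) and the
consistency of two independent engines. They emulate well-mixed,
constant-environment serial-dilution cultures with time-invariant rate
parameters and small state spaces. They do not emulate: environmental
fluctuation or stress-dependent switching (the persister model's
time-varying `S(t)` is the one exception), sequence-scale genotype
spaces, spatial structure, or measurement noise. Passing tests therefore
validate the theory and its numerics, not the fit of any particular
biological dataset.

## Numerical choices

- Integration: DOP853, `rtol 1e-10 / atol 1e-13`; the rhs is evaluated
  on the normalized state with a relaxation term `−(Σf − 1)f` so solver
  error in the conserved sum decays instead of compounding; the step is
  capped at half the fastest process time because the dense-output
  interpolant degrades on very long steps; recorded states are
  renormalized, with drift asserted below 1e-9 per unit time.
- Fixed points: pre-integration (doubling horizons until the residual is
  small) lands the solve in the basin of the stable equilibrium before a
  hybrid root polish in which the redundant conservation component is
  replaced by `Σf − 1`. Near-degenerate bridge equilibria (tiny `μ`) get
  the same polish applied to the eigenvector seed.
- Tie-breaking in orderings uses stable argsort; boundary cells are
  excluded from sector counts.
- Trajectory TSVs are written with 17 significant digits and parsed with
  round-trip float precision, so save/load is bit-exact.

## Known limitations

- The simulator's O(dt·X) rate compression is inherent to its
  discrete-time design; comparisons against continuum theory must either
  use small per-step growth or the `tau_discrete`-style matched
  prediction. No extrapolation to `dt → 0` is performed automatically.
- `tau_jacobian` rejects complex slow modes rather than handling
  oscillatory relaxation (not observed in the valid parameter ranges).
- Closed-form equilibria are limited to the 2×2 and bridge geometries;
  larger systems go through the numeric fixed point.
- The persister model has no back-switching to dormancy and no death; it
  describes the resuscitation window, not full stress cycles.
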