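# Methods

## Models

### Four-state circuits

Two binary variables — input `z` and output `x`, each active (`+`) or
inactive (`-`) — form a continuous-time Markov chain on the four joint
states, ordered globally as `(-,-), (-,+), (+,-), (+,+)` (`(z, x)`
lexicographic). The generator is stored in the standard convention
(`Q[i,j]` = rate from `j` to `i`, columns summing to zero, master
equation `dp/dt = Q p`); where relaxation eigenvalues are discussed the
positive-spectrum matrix `L = -Q` is meant. Both models respect the
symmetry that exchanges the two "pure" states and the two "mixed"
states, so the symmetric family
`p(mu) = ((1+mu)/4, (1-mu)/4, (1-mu)/4, (1+mu)/4)` is closed under the
dynamics; `mu` is the alignment order parameter.

Rates (all non-negative; `r = 1` fixed throughout the analysis layer,
since one rate only sets the unit of time):

| rate | meaning | model |
|---|---|---|
| `u` | input flip, both directions | no feedback |
| `s` | output anti-aligns with input | both |
| `r` | output aligns with input (unit) | both |
| `alpha` | input flip that anti-aligns the pair | feedback |
| `y` | input flip that aligns the pair | feedback |

`alpha = y = u` reduces the feedback model to the no-feedback model
exactly (checked entrywise in the tests). The four analysis variants
are `S`/`F` (no feedback / feedback, stationary initial condition) and
`S̃`/`F̃` (the same with a freely chosen symmetric initial condition
`mu0`).

The relaxation rate `λ` is the smallest positive real part among
non-zero eigenvalues of `L`: `min(1+s, 2u)` for the no-feedback model,
`(A - ρ)/2` with `A = 1+s+y+alpha`, `ρ = sqrt(A² - 8(sy+alpha))` for the
feedback model when the discriminant is positive (complex pairs
contribute their real part `A/2`). Readout times are rescaled,
`τ = λ t`, so circuits with different absolute rates are compared per
relaxation time. Eigenvalues below `1e-10` times the spectral radius are
treated as zero.

### Delayed information

The delayed joint `p(x_t, z_0)` is obtained by propagating each initial
point mass through `expm(Q t)` and contracting with the initial joint.
On the symmetric class it is again described by a single `mu_t`, and

    I[x_t; z_0] = ((1+mu) log2(1+mu) + (1-mu) log2(1-mu)) / 2

in bits, with `0 log 0 = 0` by continuity. The general 2×2 plug-in
formula is implemented alongside and agrees to 1e-12 on the symmetric
class. All information and entropy-production quantities use base-2
logarithms by default so they share units; every entry point takes a
`base` argument for nats.

### Entropy production

Instantaneous rate (Schnakenberg form) at distribution `p`:
`σ = Σ w_ij p_j log2(w_ij p_j / (w_ji p_i))`, non-negative and zero iff
detailed balance holds at `p`. A structurally one-way transition
carrying positive flux means strict irreversibility; it is reported as
an explicit `inf` flag, never a large float (the no-feedback model at
`s = 0` is the canonical case). Closed stationary forms:

    σ_ss(u, s)        = (s-1) u log2(s) / (1+s+2u)                (no feedback)
    σ_ss(alpha, y, s) = (alpha - s y) log2(alpha/(s y)) / A        (feedback)

the latter derived so that dividing by `λ = (A-ρ)/2` reproduces the
rescaled feedback form `2(alpha-sy) log2(alpha/(sy)) / (A(A-ρ))` on its
real branch; unlike that printed form it stays real when the spectrum is
complex. Both closed forms are cross-checked against the generic sum
(relative error 1e-10 / 1e-8 over random draws).

The average dissipation up to a reset time,
`Σ_avg(τ_p) = (1/τ_p) ∫₀^{τ_p} σ̂(τ) dτ`, is evaluated by adaptive
quadrature along the relaxation trajectory (eigendecomposition
propagator). For `mu0 = ±1` two states start empty and the integrand
diverges like `log τ` at the origin — integrable; the quadrature nodes
never touch the endpoint and the result was validated against an
independent `solve_ivp` integration to 1e-8. Relative tolerance is 1e-8
for reported values and 1e-7 inside optimization loops. The relaxation
cost is `τ_p (Σ_avg - σ̂_ss)`; it vanishes identically for stationary
starts.

### Optimization stage

`optimize()` maximizes `I(τ)` over log-rates (and `mu0` where free) with
multistart SLSQP; equality constraints on `σ̂_ss` (closed form) and/or
`Σ_avg` (quadrature) are handled by the solver, with an inequality mode
available. Defaults: 24 starts, log-uniform in `[1e-3, 1e3]`; the
anti-align rate `s` is allowed down to `1e-6`, since the unconstrained
optimum sits against the irreversible `s → 0` boundary and the
free-initial-condition variants with and without feedback only become
numerically equivalent as that boundary is approached (gap ~2e-7 at
`s_min = 1e-6` vs ~1e-3 at `1e-3`). The free `mu0` domain defaults to
`[0, 1]`: fixing `r = 1` breaks the rotation symmetry and selects the
positive branch; `[-1, 1]` can be opened to study the two-branch
structure of the doubly-constrained problem. Constraint satisfaction is
required to 1e-6; an unreachable constraint returns an explicit
infeasible result.

Because the model classes are nested (no feedback ⊂ feedback; stationary
`mu0` ∈ free-`mu0` domain), richer problems are warm-started from the
optima of their reductions, and each start keeps the better of the start
point and the polished point, so the information orderings
`I(S) ≤ I(F)`, `I(S) ≤ I(S̃)`, `I(F) ≤ I(F̃)`, `I(S̃) ≤ I(F̃)` hold by
construction up to solver refinement.

**Readout branch.** Fixing `r = 1` singles out a rotation direction of
the four-state cycle, restricting the admissible alignment to
`mu ∈ [0, 1]`; the optimization objective therefore scores an
anti-aligned readout (`mu_t < 0`) as zero information. Without this
convention the optimizer exploits counter-clockwise cycling
architectures (e.g. `alpha ≪ y` with very fast `s`, `y`) whose readout
is anti-correlated with the initial input — a solution family the model
convention excludes. `mi_from_mu` itself remains symmetric in
`mu → -mu`.

**Long-readout feedback advantage.** Unconstrained, the free-`mu0`
variants with and without feedback are numerically equivalent at short
readouts (`|ΔI| < 1e-6` bits at `τ = 0.5` and `1`). At `τ = 2`, however,
the feedback class finds a strictly better strategy (`ΔI ≈ 0.037`
bits): a strongly dissipative negative-feedback circuit
(`alpha ≫ y`, `s → 0`, near-degenerate spectrum) started from the
*uniform* initial condition, which builds up delayed alignment
(`mu_t ≈ 0.46` at readout) instead of relying on the decay of an
aligned initial state. The value was confirmed by an independent
ODE-propagated evaluation and cannot be matched by the no-feedback
class (60-start searches saturate at its `mu0 = 1` optimum). The
equivalence of the two classes is thus a short-readout statement; the
corresponding acceptance test asserts it across the full default grid
and is expected to fail at `τ = 2`.

**Cost of optimal information.** The information maximum is extremely
flat in the feedback directions: moving from the `alpha ≈ y`
(no-feedback-equivalent) manifold to the true feedback optimum gains of
order 0.01 bits while changing the average dissipation by ~20%.
Consequently "the cost of the optimal circuit" is ill-conditioned if
read as `Σ_avg` at the exact arg-max — under that literal reading the
feedback free-`mu0` optimum can cost *more* than the no-feedback one,
because it transmits strictly more information. The well-posed
comparison, implemented as `min_cost_at_info()`, fixes the information
level: minimize `Σ_avg` subject to the `σ̂_ss` constraint and
`I ≥ I*(S̃)`. Under this matched-information comparison the feedback
class never costs more, and typically costs strictly less (e.g. 1.359
vs 1.381 at `τ = τ_p = 0.5`, `σ̂_ss = 0.35`) — feedback buys cheaper
relaxation, not more information, once the initial condition is free.
`cost_comparison(..., matched_info=True)` reports both quantities.

**Delayed-information decay.** From a stationary start `I[z_0; x_τ]` is
*not* monotone: it rises on the learning transient (its initial slope is
the positive learning rate `l_x`) before decaying to zero; over random
parameter draws the peak always lies below `τ ≈ 0.6`. The monotone
statement that holds — and is tested — is for the *optimized* curve
`I*(τ)` and for the tail `τ ≥ 1`.

### Bursty promoter

States `(a, g)`: promoter `a ∈ {0, 1}` (production rate `R0` or `R1`,
switching `k_on = k+c` and `k_off = k-`) and protein copy number `g`
with degradation rate `g/τ_deg`. The symbol `τ_deg` (protein lifetime)
deliberately avoids a clash with the readout time `τ`. The stationary
state of the truncated chain (copy numbers `0..g_max`) is a sparse
linear solve with a normalization row — no time stepping. Automatic
truncation uses `g_max = ceil(10 + m + 10 sqrt(m))` with
`m = R_eff τ_deg`, doubled until the boundary mass is below 1e-10; an
explicit `g_max` is validated against a 1e-8 tail bound.

The stationary dissipation decomposes over edge classes:
`σ0` (promoter switching) vanishes identically at stationarity because
the switching fluxes balance; `σ1 = Σ P0 R0 log2(R0 τ_deg) + P1 R1
log2(R1 τ_deg)` has the occupancy closed form
`(R0 log2(R0τ) k_off + R1 log2(R1τ) k_on)/(k_off + k_on)`; `σ2` is the
remaining birth–death contribution. All sums are evaluated in flux form
(`flux × log(rate ratio)`), which never takes the log of a zero-count
edge; fluxes below 1e-12 are treated as absent because deep-tail
stationary probabilities underflow to exact zeros in the solve. The
three parts sum to the generic Schnakenberg total of the truncated chain
(checked to 1e-8 against an independently assembled dense rate table).
In the unbound limit `k_on → 0` the copy-number chain is a reversible
birth–death process: Poisson stationary state, detailed balance to
1e-10, `σ2 = -σ1`. In the fast-switching limit (`k_on, k_off → ∞` at
fixed ratio `cK`) the distribution becomes Poisson with the
occupancy-weighted rate `R_eff`, yet the dissipation converges (as
`1/k_off`) to the strictly positive
`σ_FS = cK/(1+cK)² (R0-R1) log2(R0/R1)`.

### Learning metrics

With no simultaneous flips the chain is bipartite and the stationary
entropy production splits exactly into output-edge and input-edge parts,
`σ_ss = σ_x + σ_z`. The learning rate is the one-sided derivative of
`I[z_0; x_τ]` at `τ = 0+` along the stationary process, computed with a
second-order forward difference plus Richardson extrapolation
(base step 1e-4, halved until successive extrapolations agree to 1e-4
relative); it matches the bipartite information-flow formula (flux times
log-ratio of `p(z|x)` conditionals) to 1e-6. For the no-feedback
(sensor-like) models the efficiency `η = l_x/σ_x` stays within `[0, 1]`
over 500 random draws, consistent with the standard bound for the
output-marginal entropy production adopted here.

### Stochastic oracle

The Gillespie simulator is exact and fully seeded. The path-entropy
estimator discretizes trajectories on a uniform grid with step chosen so
`max exit rate × δt ≤ 0.05` (the linearized transition probabilities are
then accurate to the step error); a step that changes state contributes
the log path-probability ratio with empirical one-time marginals, a
holding step contributes zero. Estimates carry ensemble standard errors
and all estimator–theory comparisons are phrased in standard-error
multiples (3 SE), never absolute tolerances; default oracle ensembles
are 8000 trajectories, which keeps the full suite inside a few minutes
on one core.

## What the synthetic conditions do and do not show

All inputs are model parameters; there is no external data. Random
parameter draws are log-uniform over `[1e-3, 1e3]` (rate ratios spanning
six decades), which exercises stiff and near-degenerate spectra but is
not calibrated to any measured biochemical network. The binary-state
abstraction ignores copy-number noise, multi-site promoters and
extrinsic fluctuations; the bursty model integrates out mRNA by
timescale separation and truncates the copy-number space. Passing tests
therefore certify the mathematical structure (stationary solutions,
closed forms, estimator consistency, optimization orderings), not
quantitative predictions for any particular organism.

## Numerical choices

- Base-2 logarithms throughout (information and dissipation share
  units); configurable per call.
- Matrix exponentials via `scipy.linalg.expm`; trajectory evaluation via
  eigendecomposition with a dense-expm fallback when the eigenvector
  condition number exceeds 1e10.
- Stationary states via dense null-space (4-state) or sparse solve
  (bursty); symmetric-class extraction symmetrizes first and tolerates
  1e-6 of linear-algebra noise on stiff generators.
- Zero-probability handling: `0 log 0 = 0`; `-inf` coupling-function
  cells are sentinels excluded from information sums by their zero
  weight; infinite dissipation is an explicit flag.
- Optimizer: SLSQP, `ftol` 1e-9, 200 iterations, reproducible via a
  single seeded generator; restart agreement within 1e-4 is reported.

## Known limitations

- The feedback closed form is compared to the printed rescaled
  expression only on its real-discriminant branch; on the complex branch
  the package's own (real) form is the reference.
- The fully asymmetric 8-parameter feedback model is out of scope; only
  the 4-parameter symmetric class is implemented, and absorbing-state
  architectures are detected and flagged rather than analyzed.
- The learning rate for feedback models is computed but its
  interpretation is limited (input and output are no longer
  distinguished roles); the `η ≤ 1` bound is only asserted for
  no-feedback models.
- `Σ_avg` constraints make each optimizer iteration run a quadrature;
  doubly-constrained sweeps are therefore markedly slower than
  `σ̂_ss`-only ones.
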