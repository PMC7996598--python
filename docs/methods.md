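# Methods

## Model

State: `n` OTU concentrations `x` and three nitrogen pools
`s = (s1, s2, s3)` (ammonium, nitrite, nitrate), all in g/L; time in
days. Growth of OTU `i` is a Monod factor on its group substrate times an
affine interaction term,

```
mu_i(s, x) = f_i(s) (1 + (A x)_i),   f_i(s) = mu_max_i s_g / (K_i + s_g),
```

where `s_g = s1` for AOB and `s2` for NOB. The chemostat balances are

```
dx_i/dt = (mu_i - D) x_i
ds/dt   = D (s_in e1 - s) + Y diag(mu) x
```

with `Y` the signed stoichiometry: column `j` is `(-1/y_j, +1/y_j, 0)`
for an AOB and `(0, -1/y_j, +1/y_j)` for a NOB. Columns summing to zero
encodes that every gram of substrate consumed in one oxidation step
reappears in the next pool; consequently the substrate derivatives sum to
`D (s_in - s1 - s2 - s3)` *identically* — a machine-precision invariant
the tests exploit, and the reason every steady state satisfies
`s1 + s2 + s3 = s_in`.

Assumptions: homogeneous reactor, equal in/out flow, no gas phase, no
pH/temperature dependence, interactions constant in time, and `I(0) = 1`
(growth of a vanishing community is purely substrate-limited — the
interaction term needs biomass to act through).

Negative growth: strongly negative interactions can make `mu_i < 0`. It
is passed through unchanged; biomass non-negativity is still guaranteed
because `dx_i/dt = (mu_i - D) x_i` vanishes at `x_i = 0`.

### Boundedness and non-negativity diagnostics

Three weighted sums obey exact linear dilution dynamics — for
`V1 = Σ_{G1} x_i/y_i + s1`, `V2 = Σ_{G2} x_i/y_i + s1 + s2` and
`V3 = s1 + s2 + s3`, direct substitution gives `dV/dt = D (s_in − V)` (the
growth terms cancel telescopically). Each is therefore bounded by
`max(V(0), max_t s_in(t))`; `lemma_bounds` returns these sharp values with
a `1 + 1e-9` round-off margin.

Inside that invariant box each biomass satisfies `x_j ≤ y_j V_group(j)`.
If `‖A‖_∞` times the largest such biomass bound is below 1, every
`1 + (Ax)_i` stays positive, all growth rates stay non-negative, and the
substrate pools cannot cross zero: `interaction_norm_bound` returns
`M = 1 / max_j (y_j V_bound)`. This is a *sufficient* condition exposed as
a diagnostic, not a hard gate — much larger matrices are often still well
behaved (the regime-change scenario's own matrix exceeds it).

### Numerics

LSODA (stiff-capable) with `rtol 1e-8`, `atol 1e-10`; piecewise-constant
operating schedules are integrated segment by segment so discontinuities
in `D`/`s_in` fall on solver restarts. Substrates are clipped at zero
inside the right-hand side only for evaluating `f` (solver iterates may
undershoot by round-off). Steady state is declared when `‖rhs‖_∞ < 1e-9`
holds over 10 consecutive daily outputs.

## Equilibrium analysis

At an equilibrium every active OTU grows at the dilution rate; with an
invertible active interaction block this pins the active biomasses to
`x_act = A_act^{-1}(D / f_act(s) − 1)`. Substituting into the substrate
balances (and using `s3 = s_in − s1 − s2`) leaves two rational equations
in `(s1, s2)`. The elimination is done symbolically per active set —
exact rational arithmetic, `D` and `s_in` kept symbolic — and cached, so
sweeping an operating grid only re-evaluates lambdified coefficient
functions:

- **Both groups active, dense coupling:** the first balance is linear in
  `s2` and yields the rational map `s2 = s1 / (b1 s1² + b2 s1 + b3)`;
  substituting into the second balance and cancelling the spurious root
  at `s1 = 0` left by clearing denominators gives a polynomial of degree
  ≤ 4 in `s1`. The degree bound is asserted, not assumed.
- **Both groups active, decoupled balances** (triangular/diagonal
  interaction blocks make the first balance independent of `s2`): solve
  the resulting ≤-quadratic for `s1`, then a ≤-quadratic for `s2`.
- **NOB washed out:** `s3 = 0`, `s2 = s_in − s1`, and the elimination is
  a quadratic in `s1`.
- **Total washout:** closed form `x = 0, s = (s_in, 0, 0)`.

Exact integers in the eliminated coefficients can exceed double range
even though coefficient ratios are O(1); each coefficient list is jointly
rescaled by its largest rational constant before being lowered to floats
(for the rational map, numerator and denominator share one scale so the
map's value is preserved).

Roots come from the companion matrix (`numpy.roots`); a root is accepted
as real when `|Im| < 1e-9 (1 + |Re|)`, components above `−1e-10` are
clamped to zero, and a candidate must pass `‖rhs‖_∞ < 1e-8` on the
*original* model before being kept. Stability uses the analytic Jacobian
(cross-checked against central differences in the tests): stable if all
eigenvalue real parts are below `−1e-7`, marginal within `±1e-7` — never
promoted to stable. Equilibria are deduplicated at `1e-6` in max norm.
Enumeration over the `(2^{n1}−1)(2^{n2}−1) + (2^{n1}−1) + 1` candidate
supports is guarded by a configurable cap (default `n ≤ 12`).

With `A = 0` the active-biomass formula is unavailable; the classical
break-even analysis applies: each surviving species sits at
`s_g* = D K / (mu_max − D)`, at most one survivor per group is generic
(competitive exclusion), and the fallback enumerates exactly those
single-survivor supports. Singular non-zero active blocks are skipped
with a warning (the support then carries no isolated equilibrium under
this method).

## Diagrams

The ecological diagram runs the full equilibrium analysis per grid cell
and records the survivor set of every *stable* equilibrium; the operating
diagram collapses survivor sets to CN/PN/WO (CN: some NOB survives; PN:
AOB survive, no NOB; WO: nothing). Cells with ≥ 2 stable equilibria whose
survivor sets differ are flagged bistable; cells with only marginal
equilibria are labelled `unknown` rather than guessed. The default
resolution (50×50 in the CLI) trades runtime for boundary sharpness;
tests use coarser grids.

## Optimal tracking (ASRE)

Measured abundances `z(t)` replace the mechanistic interaction factor by
per-OTU controls: growth becomes `f_i(s) u_i(t)` and the problem is

```
min ∫_0^T (x − z)ᵀ Q (x − z) + (u − 1)ᵀ R (u − 1) dt,   u_i ∈ [0, u_bar].
```

The cost norms are the standard quadratic forms: the Riccati machinery
requires quadratic costs, and nothing else is compatible with the
linear-quadratic tracker the method is built on.

**Weight convention.** `Q = q_weight · I` (default 1) acts on the biomass
tracking error; `R = blockdiag(λ1 I_{n1}, λ2 I_{n2})` (defaults `1e-4`,
`1e-5`) penalizes control deviation per functional group. This assignment
is forced by behavior: tracking happens only when the control penalty is
small relative to the (g/L)²-scale tracking benefit, and giving the NOB
the *smaller* penalty is what lets their order-of-magnitude-smaller
biomasses be tracked. With a single unit weight (`Q = R = I`) the control
cost dominates and the optimum is `u ≡ 1` — no tracking — which the
acceptance suite checks.

**Scheme.** Change of variable `v = u − 1` (so the penalized null is
`v = 0`). Freeze the current trajectory and linearize the biomass block
in state-dependent-coefficient form, `dx_i/dt = (f_i(s(t)) − D) x_i +
f_i(s(t)) x_i(t) v_i`. Both coefficients are diagonal, so the
finite-horizon linear-quadratic tracker decouples into one scalar Riccati
gain and one scalar feedforward per OTU — `2n` backward ODEs total:

```
-dP_i/dt  = 2 a_i P_i − P_i² b_i²/r_i + q_i,         P_i(T)  = 0
-dsf_i/dt = (a_i − b_i² P_i/r_i) sf_i − q_i z_i,     sf_i(T) = 0
v_i(t, x) = −(b_i/r_i)(P_i x_i + sf_i),   u = clip(1 + v, 0, u_bar).
```

Because the horizon carries no terminal cost, `P(T) = sf(T) = 0` and
every control ends at exactly `u(T) = 1`. The forward pass applies the
law in feedback on the actual state; clamping events are counted and
reported (the optimality argument only covers unsaturated arcs — clamped
stretches are a declared approximation, with no exact bounded-control
synthesis attempted).

**Stabilization.** The raw freeze–solve–resimulate fixed point is not
contractive for every weight choice: each tracker step is optimal for its
frozen linear model but can worsen the true objective, because the freeze
ignores the substrate feedback on `f(s)`. Two safeguards make the loop
robust without changing its fixed points:

- *Backtracking*: the Riccati/feedforward update is under-relaxed and a
  step is accepted only if the true objective does not increase by more
  than 0.1% relative; otherwise the step is halved (down to 1/16) and
  finally rejected as a stall, returning the last accepted iterate. In
  the unit-weight limit the very first step stalls and the returned
  control is the analytically-known optimum `u ≡ 1`.
- *Authority floor*: the SDC input coefficient uses
  `b_i = f_i max(x_i, 1e-6 g/L)`. Once an OTU is extinct its true control
  authority vanishes and the Riccati gain (`∝ 1/b`) diverges; flooring at
  a sub-detection biomass keeps gains finite exactly where state and
  reference are both numerically zero, so the floored law acts only on
  noise-level quantities.

Convergence is declared on the control *or* the output: `max|Δu| < 1e-4`
or `max|Δx| < 1e-4 g/L` between accepted iterates (cap 50 iterations).
The Riccati grid step is `min(0.1 d, T/1000)`. The reference interpolant
is linear by default (measurement days are sparse; smoother interpolants
are supported but clipped at zero when they overshoot). The initial state
takes `x` from the first measurement and `s = (s_in, 0, 0)` unless
provided. `u_bar` defaults to 10 — no mechanistic value exists; it only
encodes that growth amplification is finite, and the default is far from
active in every shipped scenario.

The scalar LQT core is validated against a direct-transcription optimum
of the same objective (generic nonlinear minimization over a control
grid) on linear and on tiny nonlinear instances; agreement is within a
fraction of a percent in the linear case and 2% L2 on the nonlinear one.

## Synthetic data

The generator's defaults *are* the study conditions: the two-member
community (AOB: `mu_max 0.77 /d, K 0.7 g/L, 1/y 3.98`; NOB:
`mu_max 1.07 /d, K 0.3 g/L, 1/y 16.12`), 300-day horizon at
`D = 0.24 /d` with the inlet raised from 1.25 to 1.95 g/L at day 150,
initial state `x = (0.1, 0.01) g/L`, `s = (1.25, 0, 0)`.

The interaction matrix of the original regime-change experiment is only
available graphically, so it is constructed **by property, not
transcription**: weak self-limitation (`−0.1`) on the diagonal keeps the
active blocks invertible, and the AOB-on-NOB coefficient `a21 < 0` is
scanned in steps of 0.25 until the equilibrium analyzer certifies
CN-stability at `(1.25, 0.24)` and PN-stability at `(1.95, 0.24)`; the
midpoint of the feasible window is kept (`a21 = −2.5`; window
`(−2.0, −3.0)`). Do not mistake these numbers for the original study's
values.

Observations: biomasses sampled every 3 days. The regime-change fixture
is noise-free (its role is a controlled recovery target); the generic
sampler applies multiplicative lognormal noise (default CV 10% — a
stand-in, as the emulated fingerprint pipeline reports no noise model)
with truncation at zero and a detection threshold (default `1e-4 g/L`)
below which values are recorded as 0. Random communities sample kinetics
log-uniformly across the span of the published tables and scale the
interaction matrix to 60% of the well-posedness diagnostic. The 3-day
cadence and the 132-day "application-like" horizon are configurable
guesses, not measured values.

What passing on these fixtures does **not** show: robustness to real
fingerprint artefacts (peak-calling noise, compositional effects, OTU
dropout correlated with abundance), to model misspecification of `f(s)`,
or to unmodelled environmental drivers. The tracking control absorbs
*any* growth-rate modulation, not specifically pairwise interactions —
the method is explanatory, not predictive.

The interaction-free recovery check uses 0.5-day sampling: with 3-day
sampling the piecewise-linear interpolation error of the fast initial
transient (not any model defect) already drives the cheaply-penalized
NOB control tens of percent from 1. Recovery statements require the
reference interpolation error to be small against the control response;
the dense noise-free fixture is the faithful reading of "data the null
model explains exactly".

## Identifiability probe

`fit_interaction_matrix` minimizes `∫ |u(t) − (1 + A x(t))| dt`
(absolute-value misfit, trapezoidal quadrature,
derivative-free Powell restarts from seeded random matrices). It reports
every start's optimum; the across-start spread is the diagnostic. On
rich noise-free gLV controls the matrix is recovered; on flat
trajectories the misfit is rank-deficient and many matrices fit equally
well. No claim is made — or should be inferred — that the true matrix is
recoverable from tracked real data.

## Known limitations

- Limit cycles are not searched for; classification is local (eigenvalue
  based), and `unknown` diagram cells are exactly the places where a
  non-equilibrium attractor could hide.
- Clamped control arcs are suboptimal by construction (no
  Pontryagin-based synthesis for active bounds).
- The well-posedness bound is sufficient only; the regime-change matrix
  itself violates it while remaining well behaved.
- Within-group coexistence under `A = 0` (identical break-evens) is a
  non-generic continuum and is represented by single-survivor supports.
- The exponential support enumeration caps at `n = 12` by default;
  communities beyond that need the cap raised explicitly and patience.
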