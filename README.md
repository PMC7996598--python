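# chemotrack

Modelling and data-driven analysis of nitrifying chemostat communities
whose members interact.

A two-step nitrification cascade runs in a continuously diluted reactor:
ammonia-oxidizing bacteria (AOB, functional group G1) convert ammonium
(s1) to nitrite (s2), nitrite-oxidizing bacteria (NOB, group G2) convert
nitrite to nitrate (s3). Each operational taxonomic unit (OTU) grows at a
Monod rate on its group's substrate, modulated by an affine generalized
Lotka–Volterra (gLV) interaction term:

```
dx_i/dt = (mu_i(s, x) - D) x_i,        mu_i(s, x) = f_i(s) (1 + Σ_j a_ij x_j)
ds/dt   = D (s_in e1 - s) + Y diag(mu) x,   f_i(s) = mu_max_i s_g / (K_i + s_g)
```

with dilution rate `D` [1/day], inlet ammonium `s_in` [g/L], signed
stoichiometry `Y` built from the yields `y_i`, and `a_ij` the effect of
OTU `j` on the growth of OTU `i`. The package provides, for this model:

- **Forward simulation** under piecewise-constant operating schedules,
  with the exact conservation law (substrate derivatives sum to
  `D (s_in − s1 − s2 − s3)`) and a-priori boundedness/non-negativity
  diagnostics.
- **Exhaustive equilibrium analysis**: for every candidate survivor set
  the state is eliminated symbolically down to a polynomial in s1
  (degree ≤ 4 when both groups persist, ≤ 2 when the NOB are washed
  out); roots are filtered for admissibility and classified by the
  eigenvalues of the analytic Jacobian.
- **Operating / ecological diagrams** over the `(s_in, D)` plane,
  labelling each cell CN (complete nitrification), PN (partial
  nitrification) or WO (washout), with survivor sets and bistability
  flags.
- **Optimal tracking (ASRE)**: given measured OTU abundances `z(t)`, the
  interaction factor is replaced by per-OTU controls `u_i(t)` and the
  constrained problem `min ∫ (x−z)ᵀQ(x−z) + (u−1)ᵀR(u−1) dt`,
  `u_i ∈ [0, u_bar]`, is solved by an approximating sequence of Riccati
  equations — 2n scalar backward ODEs per iteration thanks to the
  diagonal structure. The reconstructed `u` measures how far the data
  are from the interaction-free null, and the tracked mass balances
  reconstruct the substrate dynamics from abundance data alone.
- **A synthetic-data generator** reproducing the regime-change study
  design (300 days, operating shift at day 150 from a CN zone to a PN
  zone), random well-posed communities, and noisy sampled observations.
- **An identifiability probe** fitting constant gLV matrices to a
  reconstructed control from many random starts, reporting the
  across-start spread.

## Worked example

`examples/04_track_interactions.py` generates the regime-change dataset
(two OTUs sampled every 3 days; the tracker sees only the abundance
table) and reconstructs the growth controls:

```
generator interaction matrix:
 [[-0.1  0. ]
 [-2.5 -0.1]]
reference: 101 sampling days, 2 OTUs
converged=True after 7 iterations
objective per iteration: ['1.35', '0.00269', '0.00152', '0.00144', '0.00143', ...]
terminal controls u(T) = [1. 1.]  (always 1: no terminal cost)
control ranges: AOB [0.889, 1.137], NOB [0.000, 1.000]
substrate reconstruction error (relative L2): 0.009
```

Reading: the objective falls three orders of magnitude as the tracker
locks on. The AOB control stays near 1 (its growth needs no correction),
while the NOB control dives to 0 after the day-150 inlet shift — the data
show the NOB disappearing despite abundant nitrite, so its growth must be
suppressed, which is exactly the negative `a21` the generator used. The
three nitrogen pools are reproduced to 0.9% relative L2 even though the
tracker never saw them. Every control ends at exactly 1 because the
horizon carries no terminal cost.

The other examples show forward simulation through the operating shift
(`01`), the full equilibrium table with stability labels (`02`), an
ASCII operating diagram with its interaction-induced PN wedge (`03`),
and the identifiability probe on rich versus flat trajectories (`05`).
Each prints a short commentary of what the numbers mean.

A thin CLI wraps the same workflows
(`chemotrack simulate|equilibria|diagram|synth|track|probe-a`); every run
writes CSV artifacts plus a JSON manifest with the configuration hash and
seed.

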