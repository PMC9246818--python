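# Methods

## Model and assumptions

The package analyses a planar ODE model of a vascularised tumour growing in
a tissue of fixed total volume.  Its assumptions, in order of consequence:

1. **Constant vasculature.**  The vascular volume fraction `V0` is a
   parameter, not a state: angiogenesis and vascular remodelling are out of
   scope.  Oxygen enters only through the vasculature, at rate
   `g (1 − c) V0`, saturating at the vascular oxygen level (`c = 1`).
2. **Space competition.**  Tumour and vasculature share one unit of space;
   proliferation requires free space `S = 1 − (T + V0)` and oxygen, at rate
   `q2 c T S`.
3. **A hard hypoxia switch.**  Below the threshold `c_min` cells die at
   rate `δ1 (c_min − c)`, gated by a unit step with `H(0) = 1`.  The vector
   field is continuous (C⁰) across the switch because the death factor
   vanishes there, but not differentiable.
4. **Tied death and proliferation rates.**  `δ1 = q2` by default, reflecting
   the observed correlation between tumour proliferation and death rates.
   A decoupled `δ1` is accepted behind an explicit flag; every closed form
   that assumes the tie then falls back to a numerical path (see below).
5. **Proliferation oxygen demand.**  `q2 = q3 / k` with conversion factor
   `k`: the oxygen drawn for proliferation is proportional to the
   proliferation rate.

These assumptions confine the dynamics to the box `[0, 1 − V0] × [0, 1]`:
`T = 0` is invariant, `dc/dt > 0` at `c = 0`, `dc/dt ≤ 0` at `c = 1`, and
`dT/dt ≤ 0` at `T = 1 − V0`.  The forward-invariance of this box is a
tested property.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `c_min` | severe-hypoxia threshold (fraction of vascular O₂) | 1e-2 | fixed baseline |
| `g` | O₂ exchange rate per unit vascular volume (1/time) | 5 | fixed baseline |
| `k` | conversion factor proliferation → O₂ demand | 1e-2 | fixes `q2 = 100 q3` |
| `q1` | maintenance O₂ consumption rate | study range 1e-2…10 | tumour-specific |
| `q3` | proliferation O₂ consumption rate | study range 1e-2…10 | tumour-specific |
| `V0` | vascular volume fraction | study range (0, 5e-3] | treatment target |
| `δ1` | starvation death rate | `q2` | decoupling needs a flag |

All times are dimensionless; the `nondimensionalise` map converts a
dimensional parameter set (rates with units, total space `S_max`, vascular
oxygen `c_max*`, time scale `τ`).  The dimensionless conversion factor is
defined there as the ratio the structural identity dictates,
`k = q3/q2 = S_max/(c_max* k*)`, so that `q2 = q3/k` holds identically for
any valid dimensional input (which satisfies `q3* = q2*/k*`).

Validation is eager (constructor-time): every analysis in the package
assumes the constraints above, so a malformed set must never propagate.

## Steady states and conventions

The phase plane splits at `c = c_min`.  On the nutrient-rich side the
steady states are closed forms (SS1, SS2 in the README).  On the
nutrient-poor side, eliminating `T` between the starvation nullcline
`T(c) = (1 − V0) − (c_min/c − 1)` and the oxygen balance yields the
quadratic `Y c² − c_min X c − q3 c_min² = 0`; its coefficients are verified
symbolically (sympy) in the test suite, and the two roots give SS3/SS4.
Conventions, chosen once:

* **Switch boundary.**  A state with `c* = c_min` exactly is classified SL;
  the NL regime is the half-open band `0 ≤ c < c_min`.  At the SS2
  existence bound (`c2* = c_min`) the closed form rounds to the last ulp,
  so admissibility carries an absolute slack of 1e-12.
* **Admissibility.**  `c ∈ [−1e-12, c_min − 1e-12)` and
  `T ∈ [−1e-12, 1 − V0 + 1e-12]` for NL roots.  Roots with `T* ≈ 0`
  (within 1e-9) are kept but flagged `edge`, because the strict-vs-weak
  positivity convention for NL tumours is genuinely ambiguous.
* **Degenerate quadratic.**  `|Y|` below 1e-12 times the magnitude of its
  two addends triggers the linear solve (single root, SS4 absent); this
  surface is exactly `V0 = 2(q3 − q1)/(g + q3 − q1)`.
* **Ordering.**  The starvation nullcline is strictly increasing in `c`,
  so sorting the admissible roots by `T` or by `c` agrees; the smaller is
  SS3.
* **Decoupled `δ1`.**  No closed form is attempted: the oxygen balance is
  scanned along the general starvation nullcline on a 2000-point grid over
  `(0, c_min)` and each sign change refined by Brent's method.  Steady-state
  *locations* are independent of the `δ1/q2` ratio only when the ratio is
  1; the code path is cross-checked against the quadratic at the coupling
  point.

Every reported steady state satisfies `‖f‖∞ < 1e-10`; an independent
brute-force oracle (nullcline sign-scan plus bisection on the SL balance)
confirms on random parameter sweeps that no state is missed or invented.

## Linear stability

Analytic regime-dependent Jacobians, validated against central finite
differences (step 1e-7, agreement 1e-5 relative).  At the switch the
Jacobian is one-sided: states within 1e-9 of `c_min` are evaluated in their
own regime, and an exact-boundary request without a side raises.  SL states
use closed-form eigenvalues (the Jacobians are triangular there); NL states
use numerical eigenvalues.  Classification uses a hyperbolicity tolerance
of 1e-10 on eigenvalue real parts; a spectrum inside that band yields
`NON_HYPERBOLIC`, never an exception.

That every admissible SS3 is stable and every SS4 unstable is an **audited
numerical property, not a theorem**: the trace is provably negative at both,
but the determinant sign at SS4 is parameter-dependent in general.  The
acceptance suite sweeps 500 random parameter sets and fails loudly on any
counterexample; none has been observed.

## Time integration

* Adaptive explicit Runge–Kutta (4,5) (Dormand–Prince, scipy's `RK45`) at
  `rtol = 1e-8`, `atol = 1e-10`.  Tight tolerances matter: `c` can sit
  orders of magnitude below `c_min`, and loose error control mislabels the
  arrest mechanism.
* Crossings of `c = c_min` are located by (non-terminal) event detection;
  integration continues through the switch since the field is continuous.
* **Settle criterion.**  After arrest the solution is constant but an
  explicit method's step stays at the linear-stability bound, so a run to
  `t = 1e5` wastes ~10⁵–10⁶ steps at equilibrium.  A terminal event stops
  integration once the Newton-step norm `‖J⁻¹f‖₂ < 1e-7`.  The Newton step
  estimates the *distance to the nearest equilibrium*; the raw residual
  `‖f‖` would be the wrong metric because the integrator's error control
  leaves state noise of order `rtol·|x|` which the Jacobian (norm ∝ `q2`,
  up to 10³ here) amplifies into a parameter-dependent residual floor.
  Near a fold the Jacobian is near-singular and the event deliberately
  never fires (full-horizon integration).  Observed landing accuracy is
  ≤ 1e-7 in the state, well inside the 1e-5 used by the
  simulation-vs-analysis agreement tests.
* Convergence of a full-horizon run is declared from a trailing window (5%
  of the span): maximum relative drift < 1e-6 and final residual
  `‖f‖∞ < 1e-6` (a threshold chosen above the error-control noise floor of
  the largest admissible `q2`).  A settled run is converged by
  construction.
* Tiny negative components from round-off (≥ −1e-12) are clamped to zero;
  anything more negative is a real error and surfaces.

A caveat that follows from the settle design: an initial condition placed
*extremely* close to an unstable equilibrium (e.g. `T(0) < 1e-7`) would
settle onto it rather than integrate the slow escape.  The study's initial
condition `(T, c) = (0.05, 1)` is far from this regime.

## Growth regimes and bifurcation diagrams

A parameter point is classified by which non-trivial stable states it
supports — SS2 only (SL), SS3 only (NL), or both (BISTABLE) — computed from
admissibility plus linear stability, *not* from simulation; simulation is
the audit.  Grid scans are pure per-node computations (order-independent
output), and branch assembly for bifurcation diagrams is per-identity
collection over the `V0` grid: the closed forms and the quadratic make
continuation machinery unnecessary.  The bistable window is reported at
grid resolution.

**Basins under the default coupling.**  With `k = 1e-2` the proliferation
rate `q2 = 100 q3` exceeds every consumption rate by two orders of
magnitude, so from a small well-oxygenated initial state the tumour fills
space long before oxygen can fall below threshold: in the bistable regime
such initial conditions land on the *spatially limited* attractor, and the
hypoxic attractor's basin is reached only from low-oxygen initial states.
(Under the reciprocal coupling `q2 = k q3` the opposite holds.)  The
simulation-consistency tests therefore assert that the simulated attractor
is one of the regime's stable states, which is the claim the classification
actually licenses.

**Benchmark presets near region boundaries.**  The named presets `fig5_B`
(`V0 = 0.014, q3 = 0.8, q1 = 0.1`), `fig5_C` (`0.035, 0.5, 0.1`) and
`fig6_NL` (`V0 = 0.0022, q1 = q3 = 1`) all lie in the SL region under
these equations: at the first two the oxygen nullcline cannot reach the
hypoxic band at all, and the third sits just above (≈9% above) the SS2
existence bound `1/496`, where no hypoxic state exists yet.  They are
retained verbatim for interface compatibility, but regime-sensitive
workflows should prefer `fig3a/fig3b/fig6_BI/fig6_SL`, which sit well
inside their regions.

## Treatment sweep

The vascular-damage treatment is modelled as a monotone dose → `V` map
(default `V = V0 e^{−αD}`; any user map passing a strict-monotonicity audit
is accepted) and a **quasi-static hysteresis rule**: the tumour stays on
its branch while that branch exists and is stable, and jumps only when it
disappears.  Without hysteresis the bistable interval's behaviour — staying
on the large SL branch until it vanishes — cannot be reproduced.  The jump
of an SL tumour is identified with the SS2 existence bound; this
identification is verified numerically (bisection on admissibility agrees
with the closed form to 1e-10) rather than assumed.  The landing branch
after a jump is the unique remaining stable branch; the two-branch tie case
cannot occur in this two-attractor system but is guarded by a
nearest-in-`T` rule.  A full dynamic re-equilibration experiment (stepping
`V` down and simulating to convergence at each step) reproduces the
quasi-static path to 1e-4, including the collapse across the fold.

## Problem sizes

Defaults chosen so the whole suite runs in about a minute on one core:
residual-oracle sweeps use 100 random parameter sets with a 2000-point
scan grid; the stability audit uses 500 sets; regime scans use 100×100
grids; forward invariance uses 200 random trajectories to `t = 10³`; the
growth-curve families use all 15 parameter combinations to `t = 10⁵`
(settling early).  All random draws use fixed seeds; repeated runs are
bit-identical.

## Known limitations

* No vascular dynamics, spatial structure, or stochasticity: `V0` is a
  knob, the model is a planar ODE, and all conclusions are
  mean-field-style.
* The SS4-instability audit is numerical evidence, not proof.
* Bistable-window endpoints and regime-map boundaries are reported at grid
  resolution; no two-parameter continuation of the fold curve is provided.
* The basin structure in the bistable regime depends strongly on the
  `q2 = q3/k` coupling (see above); conclusions about *which* attractor a
  growing tumour reaches do not transfer to other couplings, although the
  steady-state structure itself is independent of `q2`.
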