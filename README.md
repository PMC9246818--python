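# vasctum

Steady-state and dynamical analysis of a minimal ODE model of **vascular
tumour growth with two distinct growth-arrest mechanisms**: arrest by
exhaustion of physical space (no cell death) and arrest by oxygen shortage
(proliferation balanced by starvation death).

## Who this is for

Mathematical oncologists and dynamical-systems modellers who need a tested,
scriptable implementation of the model — its simulations, closed-form steady
states, linear stability, growth-regime maps, bifurcation diagrams over the
vascular volume, and quasi-static sweeps emulating a vascular-damage
treatment — rather than one-off notebook code.

## The model

The tumour volume fraction `T(t)` and oxygen concentration `c(t)` (scaled by
the vascular oxygen level) evolve as

    dT/dt = q2 c T (1 − (T + V0)) − δ1 (c_min − c) H(c_min − c) T
    dc/dt = g (1 − c) V0 − q1 c T − q3 c T (1 − (T + V0))

with `H` the unit step (`H(0) = 1`).  Space is shared between the tumour and
a *constant* vascular compartment `V0`, the sole oxygen source.  Cells
consume oxygen for maintenance (`q1`) and proliferation (`q3 = q2·k` with
conversion factor `k`); below the severe-hypoxia threshold `c_min` they die
at rate `δ1 (c_min − c)`, with `δ1 = q2` by default (death and proliferation
rates tied).  Baseline constants: `c_min = 10⁻²`, `g = 5`, `k = 10⁻²`;
`q1, q3 ∈ [10⁻², 10]`, `V0 ∈ (0, 5·10⁻³]`.

Key structure:

* **SS1 = (0, 1)** — tumour-free, always a saddle (never attracts);
* **SS2 = (1 − V0, c2\*)**, `c2* = V0 / (V0 + (q1/g)(1 − V0))` — the
  space-filling (spatially limited, SL) state; exists iff
  `V0 ≥ 1 / ((g/q1)(1 − c_min)/c_min + 1)` and is then always stable;
* **SS3, SS4** — hypoxic (nutrient limited, NL) states with `c* < c_min`,
  the roots of `Y c² − c_min X c − q3 c_min² = 0` where
  `X = q1 − 3q3 + (g/c_min + q3)V0`, `Y = 2(q1 − q3) + (g + q3 − q1)V0`;
  SS3 (smaller tumour) is stable, SS4 is a saddle.

Depending on `(q1, q3, V0)` the system is in an **SL**, **NL** or
**bistable** regime.  Reducing `V` quasi-statically (vascular-damage
treatment) moves an SL tumour *up* the SS2 branch (`T* = 1 − V`) until the
existence bound is crossed, where the steady state collapses onto the much
smaller hypoxic branch — a fold-like jump — and then shrinks gradually.

## Worked example

Steady states of the bistable benchmark set `fig6_BI`
(`q1 = 1, q3 = 5, V0 = 0.0022`):

```sh
$ vasctum steady-states --params fig6_BI --out ss.json
wrote 4 steady states to ss.json
```

`ss.json` then contains (abridged):

```json
[
  {"identity": "SS1", "T": 0.0,    "c": 1.0,     "regime": "SL", "stability": "UNSTABLE"},
  {"identity": "SS2", "T": 0.9978, "c": 0.01090, "regime": "SL", "stability": "STABLE"},
  {"identity": "SS3", "T": 0.4535, "c": 0.00648, "regime": "NL", "stability": "STABLE"},
  {"identity": "SS4", "T": 0.9643, "c": 0.00968, "regime": "NL", "stability": "UNSTABLE"}
]
```

Two stable states coexist — the space-filling tumour at `T* = 0.9978`
(oxygen just above the hypoxia threshold) and the hypoxic tumour at
`T* = 0.4535` — separated by the saddle SS4: the hallmark of the bistable
regime.

A vascular-damage sweep of the spatially limited benchmark `fig6_SL`
(`q1 = 1, q3 = 9, V0 = 0.0045`):

```sh
$ vasctum treatment-sweep --params fig6_SL --start-branch SS2 \
      --v-from 0.0045 --v-to 5e-4 --steps 400 --out sweep.csv
400 steps, jumps at [248] -> sweep.csv
```

The occupied branch follows `T* = 1 − V` (rising slightly as `V` shrinks)
until step 248, where `V` crosses the critical threshold
`1/496 ≈ 2.016·10⁻³` and `T*` collapses from 0.998 to 0.223 before
continuing to decrease on the hypoxic branch.

Simulation of a sparse-vasculature tumour (`fig3a`):

```sh
$ vasctum simulate --params fig3a --out traj.csv
NUTRIENT_LIMITED: final state (T, c) = (0.09426830572, 0.005248709299)
```

Other subcommands: `stability`, `regime-map`, `bifurcation`,
`phase-portrait`.  `--params` accepts a preset name (see
`vasctum.PRESETS`) or a flat YAML/JSON file; every run writes a
`.meta.json` sidecar with the fully resolved configuration.

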