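# kaiabc-ring

A minimal Markov-state model of the KaiABC post-translational circadian
oscillator of *Synechococcus elongatus*, for people who want an
analytically tractable testbed for oscillation onset, metabolic
compensation and the thermodynamics of biochemical clocks.

KaiC hexamers live on a discretized phosphorylation ring: active
KaiA-free states `P1(φ)` and KaiA-bound states `P3(φ)` on the
phosphorylating half φ ∈ [0, π], and inactive KaiA-sequestering states
`P2(φ)` on the dephosphorylating return arc φ ∈ [π, 2π].  The occupancy
vector obeys a nonlinear master equation

    dP/dt = W(P)·P,

nonlinear only through the free-KaiA pool
`A_f = max(0, A_T − ΣP3 − ε_seq·ΣP2)`, which feeds the binding rate
`k_Af·A_f` of the `P1 → P3` edges.  Two experimentally motivated
ingredients control the clock: **differential affinity** — unbinding at
rate `k_Ab0·α^(φ−π)` with α > 1, so KaiA is captured at dawn and released
at dusk — and **ultrasensitivity** — a KaiA-free dephosphorylation rate
`k1` that antagonizes phosphorylation and makes phase progression
switch-like in `A_f`.

The library provides:

* exact and approximate closed-form stationary states (`analytic_k1_zero`
  at k1 = 0 via a constant-current ladder construction; `approx_k1` via
  the vertical-balance ansatz `k_Af·A_f·P1 = k_Ab0·α^(φ−π)·P3`), plus a
  damped-Newton reference solver that also reaches *unstable* fixed
  points;
* linear stability around those states: restricted spectrum of
  `M = W(p*) + feedback`, Hopf-type onset flag, predicted period
  `2π/|Im λ|`, bisection for critical parameter values, Gershgorin
  diagnostics;
* stiff integration of the full nonlinear dynamics with period,
  amplitude and wavepacket-velocity (angle–angular-velocity orbit)
  observables;
* edge-flux entropy production `σ̇ = Σ (J₊−J₋)·ln(J₊/J₋)` for stationary
  states and cycle averages;
* the KaiB-free ultrasensitive dose–response with two effective-Hill
  estimators;
* a shared-KaiA-pool Gillespie simulation (numba-accelerated) as the
  finite-copy-number oracle for the mean-field equations;
* parameter presets, YAML/JSON configs, sweep orchestration, and a
  `kaiabc` command-line interface.

## Worked example

Where does the clock turn on as differential affinity is increased, and
what does it cost?

```bash
$ kaiabc critical -p table_s1 --which alpha --lo 5 --hi 40
{"which": "alpha", "critical_value": 23.98681640625}

$ kaiabc stability -p table_s1 --set alpha=30
{"oscillating": true, "leading_re": 0.0010587765381565827,
 "leading_im": 0.06339239785811292,
 "predicted_period": 99.1157539306658, ...}

$ kaiabc entropy -p table_s1
{"entropy_rate": 1.7832383593302852, "mode": "stationary",
 "oscillating": false, ...}
```

At the `table_s1` operating point (K_d0 = 5, k1 = 0) the stationary state
loses stability at α ≈ 24.0; just above onset the leading eigenvalue pair
±0.0634i predicts a ~99 time-unit period, which direct simulation of the
limit cycle confirms to within 2%.  The entropy rate (here 1.78 k_B per
unit time at α = 10, still below onset) rises steeply with α and then
plateaus — sustaining the oscillation costs only a modest increment over
the driven-but-stationary regime.

The same computations from Python:

```python
from kaiabc import (get_preset, stability_report, analytic_k1_zero,
                    integrate, detect_period, default_initial_state,
                    build_state_space)

p = get_preset("table_s1").replace(alpha=30.0)
rep = stability_report(p)          # rep.oscillating -> True
fp = analytic_k1_zero(p)           # exact closed-form stationary state
space = build_state_space(p)
p0 = 0.9 * rep.fixed_point.p + 0.1 * default_initial_state(space)
traj = integrate(p, p0, t_end=60 * rep.predicted_period, n_out=3000)
print(detect_period(traj, transient_fraction=0.5).period)  # ~100.9
```

The `table_s2` preset is calibrated for the ultrasensitivity studies at
α = 10: raising `k1` carries the system through onset (critical
k1 ≈ 0.026 at K_d0 = 8, increasing with K_d0), the oscillation period is
nearly independent of K_d0 while the amplitude is not (metabolic
compensation), and σ̇ grows almost linearly in k1.

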