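# Methods

## The model

KaiC hexamers are described by a single coarse-grained coordinate, a
phosphorylation phase φ on a ring: φ = 0 is fully dephosphorylated, φ = π
fully phosphorylated, and the arc from π back to 2π is the
dephosphorylation (night) branch.  The half-ring [0, π] is discretized
into N intervals (φ_j = jπ/N) and carries two rungs of states for the
active conformation — `P1(j)` (KaiA-free) and `P3(j)` (KaiA-bound) — while
the return arc carries one rung, `P2(k)` at phase kπ/N for k = N..2N, for
the inactive, KaiB-bound conformation that sequesters KaiA.

Edges and rate laws (all rates in inverse model-time units, concentrations
in units of total KaiC):

| edge | forward | backward | meaning |
|---|---|---|---|
| `P3(j) → P3(j+1)` | `k3_fwd` | `gamma1·k3_fwd` | KaiA-assisted phosphorylation |
| `P1(j+1) → P1(j)` | `k1` | `gamma·k1 + k1_fwd` | KaiC auto-dephosphorylation |
| `P1(j) → P3(j)` | `k_Af·A_f` | `k_Ab0·α^(φ_j−π)` | KaiA binding / differential-affinity unbinding |
| `P1(j) ↔ P2(2N−j)` | `omega` | `omega` | conformational switch, active for φ_j ≥ phi0 |
| `P2(k) → P2(k+1)` | `k2_fwd` | `gamma2·k2_fwd` | dephosphorylation in the inactive form |
| `P2(2N) → P1(0)` | `omega1` | floor | complex dissociation / cycle reset |

The hydrolysis ratios γ, γ1, γ2 < 1 encode the irreversibility of the
phosphotransfer steps.  The only nonlinearity is the shared KaiA pool,

    A_f(P) = max(0, A_T − ΣP3 − eps_seq·ΣP2),

which enters the binding rate and turns the master equation into
dP/dt = W(P)·P.  Differential affinity (α > 1) makes unbinding slow at low
φ and fast near φ = π: KaiA is captured at the start of the day and
released at dusk.  The dephosphorylation rate k1 on the KaiA-free rung is
the ultrasensitivity knob: it antagonizes KaiA-assisted phosphorylation,
so net phase progression at low φ switches on only above a free-KaiA
threshold.

Two numerical floors keep every edge reversible, which the entropy
accounting requires: nominally one-way edges (the reset) carry a reverse
rate `reverse_floor` (default 1e−8), and the KaiA-binding rate is floored
at the same value so the exhausted-pool state (A_f clamped at 0, which
genuinely occurs during the night phase at strong sequestration) does not
create an infinite-affinity edge.  Entropy rates inherit an O(ln(1/floor))
sensitivity on those edges only; everything else is floor-independent for
floors ≤ 1e−6.

## Stationary states

For a *frozen* A_f the generator is linear with a unique stationary
distribution; the nonlinearity reduces to one scalar self-consistency
condition.  Three routes exploit this:

1. **Exact closed form at k1 = k1_fwd = 0** (`analytic_k1_zero`).  With no
   horizontal P1 edges, every interior P1(j) is a dead end attached
   vertically to P3(j), so KaiA exchange balances node by node:
   `k_Af·A_f·P1(φ) = k_Ab0·α^(φ−π)·P3(φ)` exactly.  The stationary network
   then carries a single circulating current J (up P3, across the switch,
   down P2, through the reset), and each rung profile is the
   constant-current ladder solution — a constant plus a geometric mode.
   Reset closure and normalization are linear in (P3(0), J) given A_f, and
   the A_f self-consistency closes the system; eliminating A_f gives a
   quadratic in b = P3(0), solved here by bracketed root finding (and
   cross-checked against a grid scan in the tests).  Profiles are
   propagated from the high-φ anchor *downward*: the forward recurrence
   multiplies the growing mode (1/γ)^j ≈ 10^26 at N = 20 and destroys
   double precision, while the backward sweep only ever multiplies the
   decaying mode.  With phi0 = π the construction is exact for any
   eps_seq (sequestration only shifts the scalar closure); with phi0 < π
   it is used in a truncated approximate mode (occupancies beyond
   j0 = ceil(N·phi0/π) set to zero) and flagged as such.

2. **Vertical-balance approximation for k1 > 0** (`approx_k1`).  The same
   balance relation is imposed as an ansatz; the two parallel rails then
   collapse into one effective ladder with φ-dependent hop rates
   `F_j = k3_fwd + (γ·k1 + k1_fwd)·ρ_j`, `B_j = γ1·k3_fwd + k1·ρ_j`, where
   ρ_j is the unbinding/binding ratio.  At k1 = 0 this reduces *exactly*
   to route 1, so its error is continuous in k1; the tests verify the
   error against the Newton fixed point decreases monotonically as
   k1 → 0.  With phi0 < π the truncation contributes an additional
   k1-independent error floor (≈ 5e−3 in max-norm at the `table_s2`
   preset, whose conformational switch is slow enough that real mass
   climbs past phi0).

3. **Damped Newton** (`numeric_fixed_point`), the reference route: Newton
   iteration on the full nonlinear system with the analytic Jacobian
   (rate matrix plus the rank-one free-KaiA feedback term), one row
   replaced by normalization, backtracking line search with projection
   onto the simplex, and a relax-then-polish fallback (integrate, then
   Newton again) for poor starting guesses.  Because Newton does not care
   about dynamical stability, it reaches the *unstable* fixed point in
   the oscillatory regime when seeded with route 1 or 2 — integration
   cannot, as it diverges to the limit cycle.  Default residual target
   1e−10·(largest rate); tests that compare routes to 1e−7 in max-norm
   request 1e−13.

## Linear stability and onset

Perturbations around p* evolve under M = W(p*) + (∂W/∂A_f)·p* ⊗ ∇A_f; the
rank-one term is the feedback of occupancy changes on the binding rate
(∂A_f/∂p is −1 on P3 nodes and −eps_seq on P2 nodes).  M has zero column
sums, so total mass is conserved and one eigenvalue is exactly 0; the
physical spectrum is computed by restricting M to the zero-sum subspace
with an orthonormal basis (no heuristic sorting of near-zero
eigenvalues).  The stationary state is oscillatory-unstable when the
leading restricted eigenvalue has positive real part (tolerance 1e−9) and
nonzero imaginary part; the predicted period is 2π/|Im λ|.  A positive
real eigenvalue with zero imaginary part would be reported as a
non-oscillatory instability rather than an infinite period (not observed
at the shipped presets).  Critical parameter values are located by
bisection on the onset flag (default relative tolerance 1e−3), verified
in the tests against dense-grid scans.  Gershgorin diagnostics use column
discs; for a bare generator every disc touches the origin from the left,
and the feedback term plus the k1-proportional off-diagonal entries push
disc radii outward — the package exposes centers, radii and the maximal
positive protrusion.

## Dynamics and cycle observables

The master equation is integrated with LSODA and the analytic Jacobian
(the KaiA exchange makes the system stiff: rates span 1e−8 to ~2e3 at the
presets); default rtol 1e−8, atol 1e−12, with Σp monitored, renormalized
beyond 1e−9 drift and a hard failure beyond 1e−6.  Periods are mean
peak-to-peak spacings of the phosphorylation signal
f(φ) = φ/π (ascending) / 2 − φ/π (descending) after discarding a leading
transient (default 30%, 50% in near-onset tests), with quadratic
interpolation of peak positions; a span below 1e−4 is classified as
stationary, and cycle-to-cycle spacing drift above 5% raises a
"not converged" error rather than returning a bogus period.  The mean
phase ⟨φ⟩ is the circular mean unwrapped along the trajectory, so the
angle–angular-velocity orbit (wavepacket velocity) is free of 2π jumps.

## Entropy production

σ̇ = Σ_edges (J₊ − J₋)·ln(J₊/J₋) with J₊ = k_fwd·p_src, J₋ = k_bwd·p_dst,
in k_B per unit model time: each edge term is nonnegative and vanishes at
detailed balance.  On a limit cycle the rate is time-averaged over an
integer number of detected cycles (trapezoid rule).  Occupancies are
floored at 1e−30 inside the flux evaluation: the integrator clips
transiently negative tail states to exactly zero, which would otherwise
make an edge affinity formally infinite while its flux contribution is
negligible.  Because the ring lumps many microscopic reactions into each
edge, σ̇ is a lower bound on the dissipation of the underlying chemistry;
it is reported as computed, with no correction.

## Parameter presets

The shipped presets are the package's own calibration, not transcribed
constants; they are chosen once to put the model in the regimes the
analysis targets, and the tests measure everything else from them.

* `table_s1` (differential-affinity studies, k1 = 0): N = 20, α base 10,
  k_Af = 100, K_d0 = 5, k3 = 1, k2 = 0.6, γ's = 0.005, ω = 1, ω1 = 3,
  eps_seq = 0, A_T = 0.3, phi0 = π.  Feedback is pure depletion of free
  KaiA by binding.  Critical α ≈ 24 at K_d0 = 5, rising steeply with K_d0
  (≈ 3 at K_d0 = 1, ≈ 220 at K_d0 = 11); period ≈ 100 time units near
  onset.  eps_seq = 0 and phi0 = π make the k1 = 0 closed form exact on
  this whole plane.
* `table_s2` (ultrasensitivity studies, α = 10): N = 20, k_Af = 200,
  K_d0 = 8, k3 = 1, k2 = 0.4, γ's = 0.01, ω = 0.1, ω1 = 2, eps_seq = 4,
  A_T = 0.6, phi0 = 0.75π.  Strong sequestration with a slow
  conformational switch closes a delayed negative-feedback loop in which
  k1 is genuinely enabling: the stationary state is stable for all
  K_d0 ≥ 1 at k1 = 0, the critical k1 grows from ≈ 0.012 (K_d0 = 2) to
  ≈ 0.046 (K_d0 = 10) — ≈ 0.026 at K_d0 = 8 — and oscillations disappear
  altogether beyond K_d0 ≈ 12.  Period ≈ 58 time units, nearly flat in
  K_d0 (≈ 2% variation from K_d0 = 1 to 8 at k1 = 0.05) while the
  amplitude changes by ≈ 30% — the metabolic-compensation signature.
* `default`: `table_s1` at α = 30, a robust oscillator for demos and the
  stochastic-convergence checks.
* The KaiB-free dose–response (switch removed, ω = ω1 = 0) is studied at
  `table_s2` with K_d0 = 10 and a residual KaiA-independent
  phosphorylation rate k1_fwd = 0.05.  Without that residual pathway the
  response steepness is dominated by KaiA titration and differential
  affinity and is nearly independent of k1; with it, the low-k1 curves
  are shallow (phosphorylation proceeds regardless of KaiA) and raising
  k1 builds the antagonistic switch, so the effective Hill number rises
  with k1 (≈ 0.9 → 1.9 → 2.0 for k1 = 0.05, 0.1, 0.2).

Mechanistic regimes worth knowing when moving away from the presets: with
fast vertical exchange and weak sequestration, k1 only damps (it drags
the packet back before the switch); the k1-enabled oscillation needs a
slow switch, deep sequestration and a stall point that clears phi0 only
when the pool is released.  If k1·K_d0/k3 exceeds the available free
KaiA, the wave stalls below the switch and oscillations die — this is the
high-k1 / high-K_d0 white region of the phase diagram.

## Ultrasensitivity estimators

Two effective-Hill-number estimators are implemented because the
"relative amplification" prescription is not uniquely determined by its
name: (i) n_eff = ln 81 / ln(EC90/EC10) from the doses at 10% and 90% of
the curve's own dynamic range (log-dose interpolation; scale-invariant),
and (ii) the maximum local slope of logit(normalized response) against
log dose, which equals n exactly for a Hill curve at every dose.  Both
recover exact Hill exponents to 2% on grids wide enough that the
endpoint normalization bias is negligible (± 3.5 decades for n = 1); (i)
is the default and integrates over the whole transition, (ii) isolates
the sharpest segment.  A plateau check (end slope per dose decade below
2% of the dynamic range) guards against unsaturated grids.

## Stochastic oracle

The direct-method Gillespie simulation runs M hexamer copies on the same
node set with a shared integer KaiA pool of round(scale·A_T) units
(scale = M by default, so one copy is concentration 1/M and total KaiC is
1 as in the mean-field equations).  Binding debits one unit; switching
into P2 debits eps_seq units, tracked as a real-valued pool debit and
clamped at zero for propensity evaluation — eps_seq is a mean-field
stoichiometry with no microscopic prescription, and this choice keeps
the M → ∞ limit exactly the master equation.  Propensities are recomputed
per event (the pool couples all binding edges); the loop is JIT-compiled
with numba when present, with an identical pure-Python fallback.  Tests
verify exponential dwell statistics on an isolated rung
(Kolmogorov–Smirnov), copy conservation, seed-reproducibility, and
monotone convergence of time-averaged occupancies to the deterministic
trajectory through M = 100, 1000, 10000.

## Problem sizes and tolerances used in the shipped tests

N = 20 (63 nodes) everywhere except N = 8 for the detailed-balance
network and N = 2 for hand-enumerated oracles.  Limit-cycle measurements
integrate 40–120 predicted periods at rtol 1e−8 and discard the first
half; stochastic runs use 300 time units (≈ 3 cycles of the default
preset).  Near-onset classification in the flag-agreement test skips
parameter draws with |Re λ| < 2e−4 — growth times there exceed any
finite simulation horizon, so neither method can decide them; the
boundary itself is located by bisection, not classification.

## Known limitations

* The ring is a single-coordinate caricature: no Ser/Thr site identities,
  no hexamer combinatorics, no KaiB binding kinetics (KaiB enters only
  through the P1→P2 switch and sequestration stoichiometry).
* σ̇ underestimates the dissipation of the full reaction network and its
  reset-edge term depends logarithmically on `reverse_floor`.
* The vertical-balance approximation degrades when the switch is slow and
  phi0 < π (occupancy beyond the truncation), exactly the `table_s2`
  regime — it remains a guess generator for Newton there, not a
  quantitative profile.
* Near onset the Hopf growth rates at the shipped presets are small
  (1e−3–1e−2), so limit-cycle convergence needs tens of periods;
  measurements quoted above state the horizons used.
* The free-KaiA clamp makes the vector field only piecewise-smooth; the
  linearization is taken on the smooth side (gradient zero when
  clamped), and stability conclusions at deeply clamped fixed points
  should be cross-checked by integration.
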