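# Methods

## Model

The package implements rate dynamics for up to three neocortical
populations: regular-spiking pyramidal cells (R), low-threshold-spiking
somatostatin interneurons (L) and fast-spiking parvalbumin interneurons (F).
A population is reduced to its instantaneous firing rate
`M_i = β_i [I_i + I_syn,i − a_i − θ_i]₊` — a rectified-linear transfer whose
threshold `θ_i` and gain `β_i` come from steady-state f–I curves.  The rate
description assumes weak spike synchrony and stationary or slowly modulated
input; it says nothing about spike timing on the millisecond scale, so sharp
transients (e.g. the brief "window of opportunity" after a step before
feed-forward FS inhibition arrives) should be read qualitatively.

Synapses carry Tsodyks–Markram short-term plasticity.  Per directed
connection the open-channel fraction `s`, the vesicle-resource fraction `x`
and the running utilization `u` evolve as

    ds/dt = −s/τ_s + u·x·M_pre
    dx/dt = (1−x)/τ_r − u·x·M_pre
    du/dt = (U−u)/τ_f + U·(1−u)·M_pre

and the synaptic current onto the target is `± g·s` (sign fixed by the
presynaptic class: excitatory for R, inhibitory for L and F).  `τ_f = 0` and
`τ_r = 0` are exact algebraic pins (`u ≡ U`, `x ≡ 1`), not small time
constants: a synapse is modeled as purely facilitating or purely depressing.
Two consequences shape everything downstream:

* a depressing synapse's steady current saturates — `g·s* → g·τ_s/τ_r` as the
  presynaptic rate grows — so depressing inhibition subtracts a constant at
  high rates (a subtractive effect) while barely-depressed inhibition just
  above recruitment divides the gain;
* a facilitating synapse's utilization grows toward
  `u* = U(1+τ_f M)/(1+U τ_f M)` on the slow `τ_f` scale, producing delayed,
  prolonged recruitment of the LTS population.

## Parameters and units

Time is in ms, currents in nA, rates in ms⁻¹ internally (×1000 = Hz at
reporting boundaries only).  The reference circuit (`reference_circuit()`)
uses thresholds/gains `θ_R=0.1, β_R=0.11; θ_L=0.05, β_L=0.32; θ_F=0.28,
β_F=0.35` and an eight-synapse connectivity (no LTS→LTS contacts; chemical
LTS-LTS synapses are rare in cortex).  The RS→LTS synapse facilitates
(`U=0.09, τ_f=670 ms`); all others depress with `τ_r` between 227 and
1250 ms; `τ_s` is 2 ms (6.3 ms for the slower LTS→RS inhibition).  The
reduced circuit (`reduced_circuit()`) keeps only RS→LTS, LTS→RS, RS→FS and
FS→LTS connections with `τ_r = 0` everywhere and couplings `g_LR=7.5,
g_RL=35, g_FR=9.3, g_LF=8`, leaving the RS→LTS utilization as the single
slow variable.

Spike-frequency adaptation is optional: `da/dt = (−a + ḡ_a M)/τ_a` with the
unadapted gain `β̃` tied to the steady gain by `β = β̃/(1+β̃ḡ_a)` (matched
gain), so steady-state rate curves are bit-identical with and without
adaptation while step responses start stronger.  Because the mapping of
adaptation strengths to the three populations is not well constrained
empirically, the strength is exposed as a per-population knob parameterized
by the gain-reduction factor `ρ = 1+β̃ḡ_a` (default `ρ = 2`) with
`τ_a = 100 ms`, a typical adaptation time scale.

## Numerics

* Integration: classic fixed-step RK4, `dt = 0.02 ms`, rates re-evaluated
  algebraically at every stage; compiled with numba.  Step-halving changes
  rate samples by `< 1e-8 ms⁻¹` on reference step responses.
* Square-wave stimuli keep a fixed cycle mean: the active amplitude is
  `mean/duty`.  Both edges are snapped to the integration grid (rejected if
  the snap would move the period by more than 0.1%), so discontinuities
  never fall inside an RK4 step; the snapped duty keeps the cycle mean
  exact.  Default frequency 3 Hz, the spike-and-wave drive regime.
* Fixed points: rectification branches are enumerated (≤ 2³ active sets);
  within a branch the synaptic variables take their closed forms and the
  active rates are solved by Powell-hybrid root-finding from a ladder of
  starts, falling back to a start seeded by a 4 s relaxation run.  A branch
  solution is accepted only if active rates are positive, silent populations
  have non-positive net drive, and the full vector field residual is below
  1e-10.  All coexisting fixed points are returned (bistability).
* Stability: the Jacobian is assembled analytically on the fixed point's
  rectification branch (chain rule through the algebraic rates); stable
  means all eigenvalue real parts `< −1e-9 ms⁻¹`.
* Attractor classification: transient discarded (default 5 s), analysis
  window 5 s; oscillatory iff the peak-to-trough RS-rate amplitude exceeds
  `ε_osc = 1e-4 ms⁻¹`; a population is active iff its mean rate exceeds
  `ε_M = 1e-5 ms⁻¹` (0.01 Hz — far below modeled rates, far above RK4
  noise).  Near the oscillation threshold the horizon doubles (up to 40 s)
  to separate decaying transients from small limit cycles.  The RS
  "more-active state" is marked by FS activity (`M_F > ε_M`); a
  median-crossing detector on `M_R` is the cross-check and agrees to within
  one sample on constructed fixtures.  Frequency comes from mean upward
  marker crossings; both estimators are exact on piecewise-constant
  fixtures.
* Thresholds and boundaries: bisection to 1e-4 nA; activation judged on the
  steady-state rate crossing `ε_M` (fixed-point route, simulation
  cross-checked); oscillation boundaries judged on simulated attractor
  classification.
* LTS recruitment delay: during the delay the RS rate is constant, so the
  (u, s) subsystem is linear and solvable in closed form; the classic
  logarithmic expression (quasi-steady s) is available via
  `psc_rise=False`.  The default resolves the few-ms postsynaptic rise as
  well and tracks simulated onsets to well under 1% across the delay range;
  the quasi-steady form deviates by ~`τ_s/t_delay`.

## Fast–slow analysis of the reduced circuit

With `C = U_LR·τ_f,LR` (60.3 ms) held fixed while `τ_f → ∞, U → 0`, the slow
flow is `du/dt ∝ −u + C·M_R(1−u)` with nullcline `u = CM_R/(1+CM_R)`.  The
fast subsystem at frozen `u` has an upper branch (LTS silent, FS active,
`M̂_R⁺ = β_R(I_R−θ_R)` independent of `u`, ending at the saddle-node `u⁺`
where the LTS-onset condition is met) and a lower branch (FS silent, LTS
active, a linear 2×2 system, ending at `u⁻` where the FS-onset condition is
met).  Slow relaxation oscillations require exactly

1. `u⁺ > u⁻` (bistability),
2. `CM̂_R⁺/(1+CM̂_R⁺) > u⁺` (the nullcline clears the upper branch, so `u`
   keeps growing there), and
3. `u⁻ > CM_os/(1+CM_os)` with `M_os` the lower-branch RS rate at `u⁻` (the
   nullcline clears the lower branch, so `u` keeps shrinking there).

The inequality orientations follow from the sign of the slow flow on each
branch and were frozen only after the closed-form prediction agreed with
direct reduced-model simulation on better than 95% of interior grid points
(17×17 over `I_R ∈ [0, 0.6]`, `I_F ∈ [0, 0.34]`, chosen to keep the check
affordable on one CPU); the disagreements sit within one grid cell of regime
boundaries, where the finite-`τ_f` system shifts edges slightly.  At the
reference oscillatory point the simulated `u_LR` excursion matches
`[u⁻, u⁺]` to better than 5%, and the relaxation period scales with
`τ_f,LR` at fixed `C` (doubling `τ_f`, halving `U` about doubles the
period).

## A deliberate finding: which regimes the reference table produces

The implemented equations reproduce, at the reference parameters, the LTS
recruitment threshold and delay theory, the RS-FS saturation theory, the
absence-seizure cycle averages, the fast (~45 Hz) oscillations at strong
recurrent RS excitation, and — in the reduced circuit — the slow
oscillation with quantitative fast–slow agreement.  The full eight-synapse
reference circuit, however, settles to a stable fixed point everywhere in
the scanned input plane: its slow-oscillation sliver is absent, and the
LTS-silent ("M_L = 0") regime along the steep input ray ends near
`I_R ≈ 0.28` rather than extending further.  This is a parameter-level
property, not a numerical artifact: silencing LTS at higher drive would
require more FS→LTS current than that depressing synapse can deliver — its
steady current saturates at `g_LF·τ_s/τ_r = 0.05 nA` — while the facilitated
RS→LTS drive keeps growing.  Strengthening the interneuron–interneuron
couplings restores the oscillatory sliver (e.g. `g_LF ≈ 25, g_FL ≈ 15`
yields one at nearby inputs), so the mechanism is present in the model
family; the reference table simply places the circuit on the stable side of
it.  The acceptance script therefore omits the full-circuit oscillation
quantities rather than report numbers the model does not produce, and the
corresponding end-to-end tests are expected to fail under the reference
table.

## Test-problem sizes

Simulation-backed checks use 6–20 s horizons at `dt = 0.02 ms` with 2–5 s
analysis windows; phase-diagram checks use coarse grids (9×9 plus targeted
refinement along the shallow input ray); the concordance check uses the
17×17 grid above; oracle-equivalence sweeps use 40 randomized circuits with
10 s relaxations.  These sizes were chosen so the full suite runs on a
single CPU in minutes while leaving every boundary estimate at least an
order of magnitude above its tolerance.

## Known limitations

* No gap junctions, no thalamocortical synapse plasticity, no synaptic
  noise, no firing-rate saturation: rates are unbounded above threshold, so
  very strong drive produces unphysiologically high rates.
* The fast–slow closed forms apply to the reduced circuit only; the full
  circuit's eight slow variables are analyzed by simulation.
* Attractor classification assumes the system has converged within the
  horizon; near saddle-nodes transients can exceed it, which is why
  boundary-adjacent grid cells are treated as uncertain.
* Rectified-linear transfer makes thresholds exact but omits smooth f–I
  curvature near threshold.
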