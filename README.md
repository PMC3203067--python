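# stpnet

Firing-rate models of neocortical circuits built from regular-spiking (RS)
pyramidal cells and two inhibitory interneuron classes — low-threshold-spiking
(LTS, somatostatin-expressing) and fast-spiking (FS, parvalbumin-expressing)
cells — coupled by synapses with Tsodyks–Markram short-term plasticity.

The scientific question the package addresses is how the two interneuron
classes control cortical activity driven by thalamic input: RS→LTS synapses
strongly *facilitate* while RS→FS and the inhibitory synapses *depress*, so the
two cell classes shape the circuit's input–output relation, its transient step
responses, and its oscillations in qualitatively different ways.  It is aimed
at computational neuroscientists who want a tested, scriptable implementation
of this model family: steady-state theory, stimulus-response simulation, phase
diagrams, and the fast–slow analysis of the facilitation-driven slow
oscillation.

## Model

Each population `i ∈ {R, L, F}` is described by its rate (ms⁻¹)

```
M_i = β_i · [ I_i + Σ_j sign_j g_ij s_ij − a_i − θ_i ]₊
```

with threshold `θ_i` (nA), gain `β_i` (ms⁻¹·nA⁻¹), optional adaptation current
`a_i`, and `[·]₊` the rectified-linear transfer.  Each synapse `i ← j` carries
the three Tsodyks–Markram variables — open-channel fraction `s`, vesicle
resources `x` (depression, recovery `τ_r`), running utilization `u`
(facilitation, recovery `τ_f`, baseline `U`):

```
ds/dt = −s/τ_s + u·x·M_j
dx/dt = (1−x)/τ_r − u·x·M_j          (x ≡ 1 when τ_r = 0)
du/dt = (U−u)/τ_f + U·(1−u)·M_j      (u ≡ U when τ_f = 0)
```

Closed-form steady states `u* = U(1+τ_f M)/(1+U τ_f M)`,
`x* = 1/(1+τ_r u* M)`, `s* = τ_s u* x* M` underpin the fixed-point solver,
the recruitment-threshold and recruitment-delay formulas, and the fast–slow
analysis of the reduced circuit, whose single slow variable (the RS→LTS
facilitation `u_LR`) drives relaxation oscillations between an FS-active and
an LTS-active branch of the fast subsystem.

Integration is classic fixed-step RK4 (default `dt = 0.02` ms) compiled with
numba; everything is deterministic.

## Worked example

```python
from stpnet import rs_lts_circuit, reduced_circuit, make_protocol, run_simulation
from stpnet.steady import lts_threshold_input, delay_time_closed_form
from stpnet.metrics import classify_attractor

circuit = rs_lts_circuit()          # RS-LTS subcircuit, g_RL=35, g_LR=7.5
th = lts_threshold_input(circuit)
print(f"LTS recruitment threshold: I_R = {th.input_threshold:.4f} nA")
print(f"delay at I_R = 0.25 nA:    {delay_time_closed_form(circuit, 0.25):.1f} ms")

traj = run_simulation(reduced_circuit(),
                      make_protocol("constant", R=0.29, F=0.232),
                      t_end=20000, record_stride=25)
rep = classify_attractor(traj, transient=10000, window=10000)
print(f"reduced circuit at (0.29, 0.232): {rep.kind}, "
      f"{rep.frequency:.2f} Hz, duty {rep.duty:.2f}")
```

prints

```
LTS recruitment threshold: I_R = 0.1765 nA
delay at I_R = 0.25 nA:    97.2 ms
reduced circuit at (0.29, 0.232): oscillatory, 1.06 Hz, duty 0.38
```

The threshold is the constant RS drive at which facilitation first recruits
the LTS population; below it LTS cells never fire, just above it they fire
only after a delay of order 100 ms (the facilitation build-up time).  At the
stated inputs the reduced three-population circuit sits in its
slow-oscillation regime: the network alternates at ~1 Hz between an FS-active
more-active state (38% of each cycle) and an LTS-active less-active state.

The same analyses are available from the shell:

```
stpnet fastslow --IR 0.29 --IF 0.232     # oscillation conditions, u+/u-
stpnet sweep --circuit reference --ray 1.4 --scan 0:0.6:0.01 --out ray.csv
stpnet phase --circuit reference --out phase.csv
stpnet simulate --circuit reduced --IR 0.29 --IF 0.232 --out trace.csv
stpnet analyze trace.csv
```

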