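"""Two-parameter phase diagrams, ray sweeps and boundary finding.

Grid points are classified by direct simulation from the long-rested state
(the dynamical ground truth; transients near saddle-nodes can be long, so
the horizon doubles when a classification looks ambiguous).  Rest labels
can be cross-validated against the fixed-point solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .circuit import CircuitSpec, NetworkState, steady_s, steady_u, steady_x
from .metrics import EPS_OSC, EPS_RATE, AttractorReport, classify_attractor
from .simulate import StimulusProtocol, Constant, simulate
from . import steady as steady_mod

__all__ = [
    "REGIME_LABELS",
    "classify_point",
    "phase_diagram",
    "ray_sweep",
    "find_activation_threshold",
    "find_oscillation_interval",
    "grr_scan",
]

REGIME_LABELS = (
    "MR=0",
    "ML=MF=0",
    "MF=0",
    "ML=0",
    "ML>0,MF>0",
    "osc",
)


def _label_from_report(rep: AttractorReport) -> str:
    if rep.oscillatory:
        return "osc"
    if "R" not in rep.active:
        return "MR=0"
    has_l = "L" in rep.active
    has_f = "F" in rep.active
    if has_l and has_f:
        return "ML>0,MF>0"
    if has_l:
        return "MF=0"
    if has_f:
        return "ML=0"
    return "ML=MF=0"


def classify_point(
    spec: CircuitSpec,
    inputs: dict[str, float],
    t_end: float = 10000.0,
    transient: float = 5000.0,
    initial: NetworkState | None = None,
) -> AttractorReport:
    """Simulate from rest (or ``initial``) and classify the attractor.

    If the window amplitude is in the ambiguous band around the oscillation
    threshold (decaying transient vs small limit cycle), the horizon is
    doubled, up to 40 s.
    """
    protocol = StimulusProtocol({k: Constant(v) for k, v in inputs.items()})
    horizon = t_end
    while True:
        traj = simulate(
            spec, protocol, t_end=horizon, record_stride=25, initial=initial
        )
        w0 = max(transient, horizon - 5000.0)
        try:
            rep = classify_attractor(traj, transient=w0, window=5000.0)
        except Exception:
            horizon *= 2
            if horizon > 40000.0:
                raise
            continue
        # ambiguity: amplitude near the threshold may be a decaying transient
        mr = traj.window(w0).rate("R") if "R" in traj.labels else None
        amp = float(mr.max() - mr.min()) if mr is not None else 0.0
        if 0.2 * EPS_OSC < amp < 5.0 * EPS_OSC and horizon < 40000.0:
            horizon *= 2
            continue
        return rep


def phase_diagram(
    spec: CircuitSpec,
    I_R_values: Sequence[float],
    I_F_values: Sequence[float],
    t_end: float = 10000.0,
    transient: float = 5000.0,
    validate_rest: bool = False,
) -> pd.DataFrame:
    """Regime label per (I_R, I_F) grid point.

    Returns a long-format table with columns I_R, I_F, label, frequency_Hz,
    duty.  With ``validate_rest`` every rest label is cross-checked against
    a stable fixed point from the steady-state solver (a ``consistent``
    column is added).
    """
    rows = []
    for i_r in I_R_values:
        for i_f in I_F_values:
            inputs = {"R": float(i_r), "F": float(i_f)}
            rep = classify_point(spec, inputs, t_end=t_end, transient=transient)
            row = {
                "I_R": float(i_r),
                "I_F": float(i_f),
                "label": _label_from_report(rep),
                "frequency_Hz": rep.frequency if rep.oscillatory else 0.0,
                "duty": rep.duty if rep.oscillatory else 0.0,
            }
            if validate_rest:
                row["consistent"] = _rest_label_consistent(spec, inputs, rep)
            rows.append(row)
    return pd.DataFrame(rows)


def _rest_label_consistent(spec, inputs, rep: AttractorReport) -> bool:
    if rep.oscillatory:
        return True
    fps = steady_mod.solve_fixed_point(spec, inputs)
    for fp in fps:
        if not fp.stable:
            continue
        if all(
            abs(fp.rates[l] - rep.rates[l]) < 1e-5 for l in spec.labels
        ):
            return True
    return False


def ray_sweep(
    spec: CircuitSpec,
    ratio: float,
    I_R_values: Sequence[float],
    t_end: float = 10000.0,
    transient: float = 5000.0,
) -> pd.DataFrame:
    """Attractor summary along the ray I_F = ratio * I_R.

    Columns: I_R, I_F, label, per-population mean/min/max rates (ms^-1),
    frequency (Hz) and duty for oscillatory points.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    rows = []
    for i_r in I_R_values:
        inputs = {"R": float(i_r), "F": ratio * float(i_r)}
        rep = classify_point(spec, inputs, t_end=t_end, transient=transient)
        row = {
            "I_R": float(i_r),
            "I_F": inputs["F"],
            "label": _label_from_report(rep),
            "frequency_Hz": rep.frequency if rep.oscillatory else 0.0,
            "duty": rep.duty if rep.oscillatory else 0.0,
        }
        for lbl in spec.labels:
            row[f"M_{lbl}"] = rep.rates.get(lbl, 0.0)
            if rep.oscillatory and lbl in rep.extrema:
                row[f"M_{lbl}_min"], row[f"M_{lbl}_max"] = rep.extrema[lbl]
            else:
                row[f"M_{lbl}_min"] = row[f"M_{lbl}_max"] = rep.rates.get(lbl, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def _steady_rate(
    spec: CircuitSpec, inputs: dict[str, float], population: str,
    t_end: float = 10000.0,
) -> float:
    """Steady-state rate of one population, by fixed-point solve with a
    simulation fallback/cross-check near degenerate points."""
    fps = [f for f in steady_mod.solve_fixed_point(spec, inputs) if f.stable]
    if len(fps) == 1:
        return fps[0].rates[population]
    rep = classify_point(spec, inputs, t_end=t_end)
    if rep.oscillatory:
        return rep.rates[population]
    if len(fps) > 1:  # choose by basin of the rested state
        for fp in fps:
            if all(abs(fp.rates[l] - rep.rates[l]) < 1e-6 for l in spec.labels):
                return fp.rates[population]
    return rep.rates[population]


def find_activation_threshold(
    spec: CircuitSpec,
    population: str,
    ratio: float,
    bracket: tuple[float, float],
    tol: float = 1e-4,
    eps_rate: float = EPS_RATE,
    method: str = "steady",
) -> float:
    """Smallest I_R on the ray I_F = ratio*I_R where ``population`` fires.

    Bisection on the steady-state rate crossing ``eps_rate``; the population
    must be silent at the low end of the bracket and active at the high end.
    ``method`` "steady" uses the fixed-point solver (cross-checked by
    simulation where ambiguous); "simulate" always relaxes by simulation.
    """
    lo, hi = bracket

    def active(i_r: float) -> bool:
        inputs = {"R": i_r, "F": ratio * i_r}
        if method == "simulate":
            rep = classify_point(spec, inputs)
            m = rep.rates[population]
        else:
            m = _steady_rate(spec, inputs, population)
        return m > eps_rate

    if active(lo) or not active(hi):
        raise ValueError("bracket does not straddle the activation boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if active(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def find_oscillation_interval(
    spec: CircuitSpec,
    ratio: float,
    bracket: tuple[float, float],
    tol: float = 1e-4,
    scan_points: int = 16,
    t_end: float = 10000.0,
    transient: float = 5000.0,
) -> tuple[float, float] | None:
    """(I_low, I_high) of the oscillatory segment on the ray, or None.

    A coarse scan of ``scan_points`` locates an oscillatory seed; both
    boundaries are then bisected to ``tol``.  Returns None when no scanned
    point is oscillatory.
    """

    def osc(i_r: float) -> bool:
        rep = classify_point(
            spec, {"R": i_r, "F": ratio * i_r}, t_end=t_end, transient=transient
        )
        return rep.oscillatory

    lo, hi = bracket
    grid = np.linspace(lo, hi, scan_points)
    flags = [osc(g) for g in grid]
    if not any(flags):
        return None
    first = int(np.argmax(flags))
    last = len(flags) - 1 - int(np.argmax(flags[::-1]))

    def bisect(a, b, want_high_osc):
        while b - a > tol:
            m = 0.5 * (a + b)
            if osc(m) == want_high_osc:
                b = m
            else:
                a = m
        return 0.5 * (a + b)

    low = grid[first] if first == 0 else bisect(grid[first - 1], grid[first], True)
    high = (
        grid[last]
        if last == len(grid) - 1
        else bisect(grid[last], grid[last + 1], False)
    )
    return float(low), float(high)


def _high_activity_state(spec: CircuitSpec, m0: float = 0.1) -> NetworkState:
    """State consistent with all populations firing at rate m0."""
    st = NetworkState.rested(spec)
    for k, syn in enumerate(spec.synapses):
        st.u[k] = steady_u(syn, m0)
        st.x[k] = steady_x(syn, m0)
        st.s[k] = steady_s(syn, m0)
    return st


def grr_scan(
    spec: CircuitSpec,
    I_R: float,
    g_RR_values: Sequence[float],
    t_end: float = 8000.0,
    transient: float = 4000.0,
) -> pd.DataFrame:
    """Attractor summary vs recurrent RS-RS efficacy, from two initial states.

    Each g_RR point is simulated from the rested state and from a
    high-activity state to expose bistability between rest and fast
    oscillation; columns report both labels, a ``bistable`` flag and the
    oscillation frequency where found.
    """
    if spec.synapse("R", "R") is None:
        raise ValueError("circuit lacks an R<-R synapse to scan")
    rows = []
    for g in g_RR_values:
        s = spec.with_synapse("R", "R", g=float(g))
        reps = {}
        for name, init in (
            ("rested", None),
            ("active", _high_activity_state(s)),
        ):
            reps[name] = classify_point(
                s, {"R": I_R}, t_end=t_end, transient=transient, initial=init
            )
        labels = {k: _label_from_report(r) for k, r in reps.items()}
        freqs = [r.frequency for r in reps.values() if r.oscillatory]
        rows.append(
            {
                "g_RR": float(g),
                "from_rested": labels["rested"],
                "from_active": labels["active"],
                "bistable": labels["rested"] != labels["active"],
                "frequency_Hz": freqs[0] if freqs else 0.0,
            }
        )
    return pd.DataFrame(rows)
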