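"""Attractor classification and oscillation/response measurements.

Rates are in ms^-1 internally; reported frequencies are in Hz.  The RS
"more-active state" of a slow oscillation is operationalized as the
interval in which the FS population is active (M_F above threshold), since
FS cells fire exactly during the RS more-active phase; a median-crossing
detector on M_R is provided as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .simulate import SquareWave, Trajectory

__all__ = [
    "EPS_RATE",
    "EPS_OSC",
    "AttractorReport",
    "InsufficientCyclesError",
    "classify_attractor",
    "oscillation_frequency_and_duty",
    "duty_from_rate_median",
    "cycle_averaged_rates",
    "measure_lts_delay",
]

#: activity threshold on rates, ms^-1 (0.01 Hz -- far below modeled rates,
#: far above the RK4 noise floor)
EPS_RATE = 1e-5
#: peak-to-trough M_R amplitude above which the window counts as oscillatory
EPS_OSC = 1e-4
#: slow/fast oscillation split, Hz
FAST_SPLIT_HZ = 15.0


class InsufficientCyclesError(RuntimeError):
    """Raised when fewer than three marker crossings fall in the window."""


@dataclass
class AttractorReport:
    kind: str  # "rest" | "oscillatory"
    active: frozenset[str]  # populations with mean rate > eps in the window
    rates: dict[str, float]  # mean rates, ms^-1
    frequency: float | None = None  # Hz, oscillatory only
    duty: float | None = None  # more-active-state fraction, oscillatory only
    extrema: dict[str, tuple[float, float]] = field(default_factory=dict)
    band: str | None = None  # "slow" | "fast", oscillatory only

    @property
    def oscillatory(self) -> bool:
        return self.kind == "oscillatory"


def _analysis_window(traj: Trajectory, transient: float, window: float) -> Trajectory:
    t0 = traj.times[0] + transient
    w = traj.window(t0, t0 + window)
    if len(w.times) < 8:
        raise ValueError("trajectory shorter than transient + window")
    return w


def classify_attractor(
    traj: Trajectory,
    transient: float = 5000.0,
    window: float = 5000.0,
    eps_rate: float = EPS_RATE,
    eps_osc: float = EPS_OSC,
) -> AttractorReport:
    """Label the post-transient attractor as rest or oscillatory.

    Oscillatory iff the peak-to-trough M_R amplitude within the analysis
    window exceeds ``eps_osc``; a population counts as active when its mean
    rate exceeds ``eps_rate``.
    """
    w = _analysis_window(traj, transient, window)
    mr = w.rate("R") if "R" in w.labels else w.rates[:, 0]
    amp = float(mr.max() - mr.min())
    means = {lbl: float(w.rate(lbl).mean()) for lbl in w.labels}
    active = frozenset(l for l, m in means.items() if m > eps_rate)
    if amp <= eps_osc:
        return AttractorReport(kind="rest", active=active, rates=means)
    freq, duty = oscillation_frequency_and_duty(
        traj, transient, window, eps_rate=eps_rate
    )
    extrema = {
        lbl: (float(w.rate(lbl).min()), float(w.rate(lbl).max())) for lbl in w.labels
    }
    return AttractorReport(
        kind="oscillatory",
        active=active,
        rates=means,
        frequency=freq,
        duty=duty,
        extrema=extrema,
        band="fast" if freq > FAST_SPLIT_HZ else "slow",
    )


def _marker_series(w: Trajectory, eps_rate: float) -> tuple[np.ndarray, float]:
    """Series marking the RS more-active state and its on-threshold.

    Uses M_F > eps when an FS population is present and intermittently
    active; otherwise falls back to M_R against its window midrange.
    """
    if "F" in w.labels:
        mf = w.rate("F")
        if mf.max() > eps_rate and mf.min() <= eps_rate:
            return mf, eps_rate
    mr = w.rate("R")
    return mr, 0.5 * (float(mr.max()) + float(mr.min()))


def oscillation_frequency_and_duty(
    traj: Trajectory,
    transient: float = 5000.0,
    window: float = 5000.0,
    eps_rate: float = EPS_RATE,
) -> tuple[float, float]:
    """(frequency Hz, more-active-state duty fraction) of a limit cycle.

    The period is the mean spacing of upward crossings of the marker series
    (FS activity where available); the duty is the fraction of time the
    marker is above threshold.
    """
    w = _analysis_window(traj, transient, window)
    series, level = _marker_series(w, eps_rate)
    above = series > level
    ups = np.flatnonzero(~above[:-1] & above[1:])
    if len(ups) < 3:
        raise InsufficientCyclesError(
            f"only {len(ups)} upward crossings in the window; widen the window"
        )
    period = float(np.mean(np.diff(w.times[ups])))
    # duty over whole periods only, to avoid edge bias
    seg = slice(ups[0], ups[-1])
    duty = float(np.mean(above[seg]))
    return 1000.0 / period, duty


def duty_from_rate_median(
    traj: Trajectory, transient: float = 5000.0, window: float = 5000.0
) -> float:
    """Cross-check duty estimator: fraction of time M_R is above midrange."""
    w = _analysis_window(traj, transient, window)
    mr = w.rate("R")
    level = 0.5 * (float(mr.max()) + float(mr.min()))
    above = mr > level
    ups = np.flatnonzero(~above[:-1] & above[1:])
    if len(ups) < 2:
        raise InsufficientCyclesError("fewer than two cycles for the duty cross-check")
    return float(np.mean(above[ups[0] : ups[-1]]))


def cycle_averaged_rates(
    traj: Trajectory,
    period: float | None = None,
    n_cycles: int = 10,
    transient: float = 3000.0,
) -> dict[str, float]:
    """Time-averaged rates <M> over the final n whole stimulus cycles.

    For a periodic (square-wave) protocol the averaging window is an integer
    number of periods taken after the transient; the protocol's period is
    used unless one is given explicitly.
    """
    if period is None:
        period = traj.protocol.period
        if period is None:
            raise ValueError("protocol is not periodic; pass the period explicitly")
    t_end = traj.times[-1]
    t0 = t_end - n_cycles * period
    if t0 < traj.times[0] + transient:
        raise ValueError("trajectory too short for the requested cycles + transient")
    w = traj.window(t0, t_end)
    out = {}
    for lbl in w.labels:
        out[lbl] = float(np.trapezoid(w.rate(lbl), w.times) / (w.times[-1] - w.times[0]))
    return out


def measure_lts_delay(traj: Trajectory, eps_rate: float = EPS_RATE) -> float:
    """Time from step onset to LTS recruitment; +inf if LTS never fire."""
    wf = traj.protocol.waveform("R")
    onset = getattr(wf, "onset", 0.0)
    ml = traj.rate("L")
    idx = np.flatnonzero((traj.times >= onset) & (ml > eps_rate))
    if idx.size == 0:
        return math.inf
    return float(traj.times[idx[0]] - onset)
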