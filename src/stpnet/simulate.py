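"""Fixed-step RK4 simulation of the circuit under stimulus protocols.

The integrator is classic fourth-order Runge-Kutta with dt = 0.02 ms by
default; rates are recomputed algebraically at every stage evaluation.
Stimulus discontinuities (step onsets, square-wave edges) should land on
grid points -- for square waves choose dt dividing the period, which holds
for the defaults (3 Hz, dt = 0.02 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import _kernel
from .circuit import CircuitSpec, NetworkState

__all__ = [
    "Waveform",
    "Constant",
    "Step",
    "SquareWave",
    "StimulusProtocol",
    "make_protocol",
    "Trajectory",
    "simulate",
]


@dataclass(frozen=True)
class Constant:
    amplitude: float  # nA

    def __call__(self, t: float) -> float:
        return self.amplitude

    _kind = 0

    def _params(self) -> tuple[float, float, float]:
        return (self.amplitude, 0.0, 0.0)


@dataclass(frozen=True)
class Step:
    amplitude: float  # nA
    onset: float = 0.0  # ms

    def __call__(self, t: float) -> float:
        return self.amplitude if t >= self.onset else 0.0

    _kind = 1

    def _params(self) -> tuple[float, float, float]:
        return (self.amplitude, self.onset, 0.0)


@dataclass(frozen=True)
class SquareWave:
    """Periodic square wave with fixed cycle mean.

    The active-phase amplitude is mean/duty, so reducing the duty cycle at
    fixed mean raises the pulse amplitude (absence-seizure-like thalamic
    drive; default frequency 3 Hz).
    """

    mean: float  # nA, cycle average <I>
    frequency: float = 3.0  # Hz
    duty: float = 0.1  # active-phase fraction of each period

    def __post_init__(self) -> None:
        if not 0.0 < self.duty <= 1.0:
            raise ValueError("duty must lie in (0, 1]")
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")

    @property
    def period(self) -> float:
        return 1000.0 / self.frequency  # ms

    @property
    def active_amplitude(self) -> float:
        return self.mean / self.duty

    def __call__(self, t: float) -> float:
        return self.active_amplitude if (t % self.period) < self.duty * self.period else 0.0

    _kind = 2

    def _params(self) -> tuple[float, float, float]:
        return (self.mean, self.period, self.duty)


Waveform = Constant | Step | SquareWave


@dataclass(frozen=True)
class StimulusProtocol:
    """Per-population stimulus waveforms; omitted populations receive 0 nA."""

    waveforms: Mapping[str, Waveform] = field(default_factory=dict)

    def waveform(self, label: str) -> Waveform:
        return self.waveforms.get(label, Constant(0.0))

    def currents(self, labels, t: float) -> dict[str, float]:
        return {lbl: self.waveform(lbl)(t) for lbl in labels}

    @property
    def period(self) -> float | None:
        """Common stimulus period in ms, or None if aperiodic."""
        periods = [w.period for w in self.waveforms.values() if isinstance(w, SquareWave)]
        return periods[0] if periods else None


def make_protocol(kind: str, **params) -> StimulusProtocol:
    """Convenience constructor for single-population protocols.

    ``make_protocol("step", R=0.5)`` or ``make_protocol("square", R=0.35,
    duty=0.1, frequency=3.0)``; keyword names are population labels mapped
    to amplitudes (means for square waves).
    """
    duty = params.pop("duty", 0.1)
    frequency = params.pop("frequency", 3.0)
    onset = params.pop("onset", 0.0)
    waveforms: dict[str, Waveform] = {}
    for lbl, amp in params.items():
        if kind == "constant":
            waveforms[lbl] = Constant(amp)
        elif kind == "step":
            waveforms[lbl] = Step(amp, onset)
        elif kind == "square":
            waveforms[lbl] = SquareWave(mean=amp, frequency=frequency, duty=duty)
        else:
            raise ValueError(f"unknown protocol kind {kind!r}")
    return StimulusProtocol(waveforms=waveforms)


@dataclass
class Trajectory:
    """Uniformly sampled time series of rates and state variables."""

    times: np.ndarray  # ms
    rates: np.ndarray  # (n, npop), ms^-1
    states: np.ndarray  # (n, 3*nsyn + npop)
    labels: list[str]
    spec: CircuitSpec
    protocol: StimulusProtocol
    dt: float  # integration step, ms

    def rate(self, label: str) -> np.ndarray:
        return self.rates[:, self.labels.index(label)]

    def _syn_index(self, post: str, pre: str) -> int:
        for k, syn in enumerate(self.spec.synapses):
            if syn.post == post and syn.pre == pre:
                return k
        raise KeyError(f"no synapse {post}<-{pre}")

    def s(self, post: str, pre: str) -> np.ndarray:
        return self.states[:, self._syn_index(post, pre)]

    def x(self, post: str, pre: str) -> np.ndarray:
        return self.states[:, len(self.spec.synapses) + self._syn_index(post, pre)]

    def u(self, post: str, pre: str) -> np.ndarray:
        return self.states[:, 2 * len(self.spec.synapses) + self._syn_index(post, pre)]

    def adaptation(self, label: str) -> np.ndarray:
        return self.states[:, 3 * len(self.spec.synapses) + self.labels.index(label)]

    def final_state(self) -> NetworkState:
        n = len(self.spec.synapses)
        z = self.states[-1]
        return NetworkState(
            s=z[:n].copy(), x=z[n : 2 * n].copy(), u=z[2 * n : 3 * n].copy(),
            a=z[3 * n :].copy(),
        )

    def window(self, t_start: float, t_stop: float | None = None) -> "Trajectory":
        mask = self.times >= t_start
        if t_stop is not None:
            mask &= self.times <= t_stop
        return Trajectory(
            times=self.times[mask], rates=self.rates[mask], states=self.states[mask],
            labels=self.labels, spec=self.spec, protocol=self.protocol, dt=self.dt,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: time plus named rate/state columns (units in names)."""
        data = {"time_ms": self.times}
        for lbl in self.labels:
            data[f"M_{lbl}_per_ms"] = self.rate(lbl)
        for syn in self.spec.synapses:
            key = f"{syn.post}{syn.pre}"
            data[f"s_{key}"] = self.s(syn.post, syn.pre)
            if syn.tau_r > 0:
                data[f"x_{key}"] = self.x(syn.post, syn.pre)
            if syn.tau_f > 0:
                data[f"u_{key}"] = self.u(syn.post, syn.pre)
        for lbl in self.labels:
            if self.spec.populations[lbl].adaptation:
                data[f"a_{lbl}_nA"] = self.adaptation(lbl)
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _pack_state(spec: CircuitSpec, state: NetworkState) -> np.ndarray:
    return np.concatenate([state.s, state.x, state.u, state.a])


def simulate(
    spec: CircuitSpec,
    protocol: StimulusProtocol,
    t_end: float,
    dt: float = 0.02,
    initial: NetworkState | None = None,
    t_start: float = 0.0,
    record_stride: int = 1,
) -> Trajectory:
    """Integrate the model with RK4 and return the sampled trajectory.

    The default initial state is the long-rested network (s=0, x=1, u=U,
    a=0).  ``record_stride`` subsamples the stored output (the integration
    step is always dt).
    """
    if not t_end > t_start:
        raise ValueError("t_end must exceed t_start")
    if not dt > 0:
        raise ValueError("dt must be positive")
    state = NetworkState.rested(spec) if initial is None else initial
    state.validate(spec)
    labels, pop_arrays, syn_arrays = _kernel.pack_circuit(spec)
    npop = len(labels)
    skind = np.zeros(npop, dtype=np.int64)
    sp1 = np.zeros(npop)
    sp2 = np.zeros(npop)
    sp3 = np.ones(npop)
    for i, lbl in enumerate(labels):
        wf = protocol.waveform(lbl)
        skind[i] = wf._kind
        sp1[i], sp2[i], sp3[i] = wf._params()
        if isinstance(wf, SquareWave):
            # snap both edges to the integration grid (cycle mean preserved:
            # the active amplitude is mean/duty with the snapped duty)
            period_n = round(wf.period / dt)
            active_n = round(wf.duty * wf.period / dt)
            if period_n < 2 or active_n < 1 or active_n > period_n:
                raise ValueError("square wave unresolvable at this dt")
            snapped = period_n * dt
            if abs(snapped - wf.period) > 1e-3 * wf.period:
                raise ValueError("dt too coarse to align the square-wave period")
            sp2[i] = snapped
            sp3[i] = active_n / period_n
    nsteps = int(round((t_end - t_start) / dt))
    z0 = _pack_state(spec, state)
    times, rates, states = _kernel.integrate(
        *pop_arrays, *syn_arrays, skind, sp1, sp2, sp3,
        z0, t_start, dt, nsteps, record_stride,
    )
    bad_rows = np.flatnonzero(~np.all(np.isfinite(states), axis=1))
    if bad_rows.size:
        j = int(bad_rows[0])
        var = int(np.flatnonzero(~np.isfinite(states[j]))[0])
        raise FloatingPointError(
            f"non-finite state variable {var} at t ~ {times[j]:.3f} ms"
        )
    return Trajectory(
        times=times, rates=rates, states=states, labels=list(labels),
        spec=spec, protocol=protocol, dt=dt,
    )
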