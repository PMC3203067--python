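"""Deterministic synthetic fixtures for tests and estimator validation.

Everything here is seeded; the model itself is deterministic and uses no
randomness.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .circuit import CircuitSpec, reference_circuit
from .simulate import StimulusProtocol, Trajectory

__all__ = [
    "square_labeled_trace",
    "randomized_circuit",
    "rest_trace",
]


def _trajectory_from_rates(times: np.ndarray, rates: dict[str, np.ndarray]) -> Trajectory:
    labels = list(rates)
    arr = np.column_stack([rates[l] for l in labels])
    return Trajectory(
        times=times, rates=arr, states=np.zeros((len(times), 0)),
        labels=labels, spec=None, protocol=StimulusProtocol({}),
        dt=float(times[1] - times[0]),
    )


def square_labeled_trace(
    period: float = 200.0,
    active: float = 60.0,
    t_end: float = 12000.0,
    dt: float = 0.5,
    seed: int = 1,
    noise: float = 0.0,
) -> Trajectory:
    """Piecewise-constant oscillation with known period and duty.

    M_F is positive during the first ``active`` ms of each period (the RS
    more-active state) and zero otherwise; M_R alternates between two
    positive levels in phase with M_F.  Optional additive noise (uniform,
    seeded) stays far below the level separation so the exact duty
    ``active/period`` is recoverable.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    phase = times % period
    on = phase < active
    m_f = np.where(on, 0.02, 0.0)
    m_r = np.where(on, 0.03, 0.01)
    m_l = np.where(on, 0.0, 0.015)
    if noise:
        m_r = m_r + rng.uniform(-noise, noise, m_r.shape)
    return _trajectory_from_rates(times, {"R": m_r, "L": m_l, "F": m_f})


def rest_trace(
    level: float = 0.012, t_end: float = 12000.0, dt: float = 0.5, seed: int = 1
) -> Trajectory:
    """Constant-rate trace (RS active, interneurons silent)."""
    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    flat = np.full_like(times, level)
    zero = np.zeros_like(times)
    return _trajectory_from_rates(times, {"R": flat, "L": zero, "F": zero})


def randomized_circuit(seed: int, rel: float = 0.1) -> CircuitSpec:
    """Reference circuit with every efficacy perturbed by +-``rel`` uniform."""
    rng = np.random.default_rng(seed)
    spec = reference_circuit()
    syns = tuple(
        replace(s, g=s.g * float(1.0 + rng.uniform(-rel, rel))) for s in spec.synapses
    )
    return CircuitSpec(populations=dict(spec.populations), synapses=syns)
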