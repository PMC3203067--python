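"""JIT-compiled fixed-step RK4 integration kernel.

The circuit is flattened to plain arrays so the integrator loop compiles
with numba.  State packing: z = [s(0..nsyn), x(0..nsyn), u(0..nsyn),
a(0..npop)].  Pinned variables (x when tau_r = 0, u when tau_f = 0, a
without adaptation) simply carry zero derivatives and keep their exact
pinned values.

Stimulus waveforms are encoded per population as
(kind, p1, p2, p3):
  kind 0  constant:   I = p1
  kind 1  step:       I = p1 for t >= p2, else 0
  kind 2  square:     mean p1, period p2 ms, duty p3;
                      I = p1/p3 during the first duty fraction of each
                      period (so the cycle mean is exactly p1).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pack_circuit", "integrate"]


def pack_circuit(spec):
    """Flatten a CircuitSpec into the arrays the kernel consumes."""
    labels = list(spec.labels)
    idx = {lbl: i for i, lbl in enumerate(labels)}
    npop = len(labels)
    nsyn = len(spec.synapses)
    theta = np.array([spec.populations[l].theta for l in labels])
    gain = np.array([spec.populations[l].gain for l in labels])
    has_ad = np.zeros(npop, dtype=np.int64)
    tau_a = np.ones(npop)
    gbar_a = np.zeros(npop)
    for i, l in enumerate(labels):
        ad = spec.populations[l].adaptation
        if ad is not None:
            has_ad[i] = 1
            tau_a[i] = ad.tau_a
            gbar_a[i] = ad.gbar_a
    pre = np.array([idx[s.pre] for s in spec.synapses], dtype=np.int64)
    post = np.array([idx[s.post] for s in spec.synapses], dtype=np.int64)
    sg = np.array([s.sign * s.g for s in spec.synapses])
    tau_s = np.array([s.tau_s for s in spec.synapses])
    tau_f = np.array([s.tau_f for s in spec.synapses])
    tau_r = np.array([s.tau_r for s in spec.synapses])
    U = np.array([s.U for s in spec.synapses])
    if nsyn == 0:  # keep numba happy with non-empty arrays
        pre = post = np.zeros(0, dtype=np.int64)
    return (
        labels,
        (theta, gain, has_ad, tau_a, gbar_a),
        (pre, post, sg, tau_s, tau_f, tau_r, U),
    )


@njit(cache=True, fastmath=True, inline="always")
def _stimulus(kind, p1, p2, p3, t):
    if kind == 0:
        return p1
    if kind == 1:
        return p1 if t >= p2 else 0.0
    ph = t % p2
    return p1 / p3 if ph < p3 * p2 else 0.0


@njit(cache=True, fastmath=True, inline="always")
def _rates(theta, gain, pre, post, sg, z, nsyn, npop, I, M):
    for i in range(npop):
        M[i] = I[i] - z[3 * nsyn + i] - theta[i]
    for k in range(nsyn):
        M[post[k]] += sg[k] * z[k]
    for i in range(npop):
        v = gain[i] * M[i]
        M[i] = v if v > 0.0 else 0.0


@njit(cache=True, fastmath=True, inline="always")
def _rhs(theta, gain, has_ad, tau_a, gbar_a,
         pre, post, sg, tau_s, tau_f, tau_r, U,
         skind, sp1, sp2, sp3, t, z, dz, I, M):
    npop = theta.shape[0]
    nsyn = sg.shape[0]
    for i in range(npop):
        I[i] = _stimulus(skind[i], sp1[i], sp2[i], sp3[i], t)
    _rates(theta, gain, pre, post, sg, z, nsyn, npop, I, M)
    for k in range(nsyn):
        m = M[pre[k]]
        s = z[k]
        x = z[nsyn + k]
        u = z[2 * nsyn + k]
        dz[k] = -s / tau_s[k] + u * x * m
        dz[nsyn + k] = (1.0 - x) / tau_r[k] - u * x * m if tau_r[k] > 0.0 else 0.0
        dz[2 * nsyn + k] = (
            (U[k] - u) / tau_f[k] + U[k] * (1.0 - u) * m if tau_f[k] > 0.0 else 0.0
        )
    for i in range(npop):
        a = z[3 * nsyn + i]
        dz[3 * nsyn + i] = (
            (-a + gbar_a[i] * M[i]) / tau_a[i] if has_ad[i] == 1 else 0.0
        )


@njit(cache=True, fastmath=True)
def integrate(theta, gain, has_ad, tau_a, gbar_a,
              pre, post, sg, tau_s, tau_f, tau_r, U,
              skind, sp1, sp2, sp3,
              z0, t0, dt, nsteps, stride):
    """Classic RK4 from t0 over nsteps of size dt, recording every ``stride``.

    Returns (times, rates, states); row 0 is the initial condition and the
    final step is always recorded.  Aborts (flag in times[-1] = nan) is not
    used -- non-finite states raise at the python layer after return.
    """
    npop = theta.shape[0]
    nsyn = sg.shape[0]
    nz = z0.shape[0]
    nrec = nsteps // stride + 1
    if nsteps % stride != 0:
        nrec += 1
    times = np.empty(nrec)
    rates = np.empty((nrec, npop))
    states = np.empty((nrec, nz))
    z = z0.copy()
    k1 = np.empty(nz)
    k2 = np.empty(nz)
    k3 = np.empty(nz)
    k4 = np.empty(nz)
    ztmp = np.empty(nz)
    I = np.empty(npop)
    M = np.empty(npop)

    row = 0
    t = t0
    # record initial point
    for i in range(npop):
        I[i] = _stimulus(skind[i], sp1[i], sp2[i], sp3[i], t)
    _rates(theta, gain, pre, post, sg, z, nsyn, npop, I, M)
    times[row] = t
    for i in range(npop):
        rates[row, i] = M[i]
    for j in range(nz):
        states[row, j] = z[j]
    row += 1

    for step in range(1, nsteps + 1):
        t = t0 + (step - 1) * dt
        _rhs(theta, gain, has_ad, tau_a, gbar_a, pre, post, sg, tau_s, tau_f,
             tau_r, U, skind, sp1, sp2, sp3, t, z, k1, I, M)
        for j in range(nz):
            ztmp[j] = z[j] + 0.5 * dt * k1[j]
        _rhs(theta, gain, has_ad, tau_a, gbar_a, pre, post, sg, tau_s, tau_f,
             tau_r, U, skind, sp1, sp2, sp3, t + 0.5 * dt, ztmp, k2, I, M)
        for j in range(nz):
            ztmp[j] = z[j] + 0.5 * dt * k2[j]
        _rhs(theta, gain, has_ad, tau_a, gbar_a, pre, post, sg, tau_s, tau_f,
             tau_r, U, skind, sp1, sp2, sp3, t + 0.5 * dt, ztmp, k3, I, M)
        for j in range(nz):
            ztmp[j] = z[j] + dt * k3[j]
        _rhs(theta, gain, has_ad, tau_a, gbar_a, pre, post, sg, tau_s, tau_f,
             tau_r, U, skind, sp1, sp2, sp3, t + dt, ztmp, k4, I, M)
        for j in range(nz):
            z[j] += dt * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j]) / 6.0
        if step % stride == 0 or step == nsteps:
            tnow = t0 + step * dt
            for i in range(npop):
                I[i] = _stimulus(skind[i], sp1[i], sp2[i], sp3[i], tnow)
            _rates(theta, gain, pre, post, sg, z, nsyn, npop, I, M)
            times[row] = tnow
            for i in range(npop):
                rates[row, i] = M[i]
            for j in range(nz):
                states[row, j] = z[j]
            row += 1
    return times[:row], rates[:row], states[:row]
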