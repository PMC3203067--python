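"""Fixed points, thresholds, asymptotics and linear stability.

Fixed points are found by enumerating rectification branches (candidate
sets of active populations).  Within a branch the synaptic variables take
their closed-form steady states

    u* = U(1 + tau_f M)/(1 + U tau_f M),   x* = 1/(1 + tau_r u* M),
    s* = tau_s u* x* M,

so the problem reduces to root-finding on the active rates (at most three
unknowns).  A candidate is accepted only if all assumed-active rates are
positive and every assumed-silent population has net drive <= 0.  Several
consistent fixed points may coexist (bistability); all are returned.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .circuit import (
    CircuitSpec,
    NetworkState,
    SynapseParams,
    derivatives,
    population_rates,
    steady_s,
    steady_u,
    steady_x,
)

__all__ = [
    "SteadyStateResult",
    "ThresholdResult",
    "solve_fixed_point",
    "stability_eigenvalues",
    "lts_threshold_input",
    "rs_gain_at_lts_threshold",
    "fs_max_rate",
    "delay_time_closed_form",
    "detect_rr_bistability",
]

#: stability tolerance on eigenvalue real parts, ms^-1
STABILITY_TOL = 1e-9


@dataclass
class SteadyStateResult:
    rates: dict[str, float]  # ms^-1
    state: NetworkState
    active: frozenset[str]
    eigenvalues: np.ndarray
    stable: bool

    def __repr__(self) -> str:  # compact, readable in reports
        r = ", ".join(f"M_{k}={v:.5g}" for k, v in self.rates.items())
        return f"SteadyStateResult({r}, active={sorted(self.active)}, stable={self.stable})"


@dataclass
class ThresholdResult:
    input_threshold: float  # nA
    rate_at_threshold: float  # ms^-1, presynaptic drive rate at onset
    population: str  # which population turns on
    attained: bool = True  # False => never recruited at any finite input


def _steady_state_from_rates(
    spec: CircuitSpec, rates: Mapping[str, float]
) -> NetworkState:
    n = len(spec.synapses)
    s = np.empty(n)
    x = np.empty(n)
    u = np.empty(n)
    for k, syn in enumerate(spec.synapses):
        m = rates[syn.pre]
        u[k] = steady_u(syn, m)
        x[k] = steady_x(syn, m)
        s[k] = steady_s(syn, m)
    a = np.zeros(len(spec.labels))
    for i, lbl in enumerate(spec.labels):
        ad = spec.populations[lbl].adaptation
        if ad is not None:
            a[i] = ad.gbar_a * rates[lbl]
    return NetworkState(s=s, x=x, u=u, a=a)


def _net_drive(spec, state, inputs, lbl) -> float:
    """I + synaptic current - a - theta for one population."""
    d = inputs.get(lbl, 0.0) - spec.populations[lbl].theta
    for k, syn in enumerate(spec.synapses):
        if syn.post == lbl:
            d += syn.sign * syn.g * state.s[k]
    d -= state.a[spec.labels.index(lbl)]
    return d


def solve_fixed_point(
    spec: CircuitSpec,
    inputs: Mapping[str, float],
    active_set: Sequence[str] | None = None,
    rate_starts: Sequence[float] = (0.002, 0.01, 0.05, 0.2, 1.0),
) -> list[SteadyStateResult]:
    """All self-consistent fixed points of the system under constant inputs.

    Returns an empty list if no branch admits a consistent fixed point
    (callers may fall back to relaxation by simulation).
    """
    labels = list(spec.labels)
    candidates = (
        [tuple(sorted(active_set))]
        if active_set is not None
        else [
            tuple(sorted(sub))
            for r in range(len(labels) + 1)
            for sub in itertools.combinations(labels, r)
        ]
    )
    found: list[SteadyStateResult] = []
    seeds: list[dict[str, float]] | None = None
    for attempt in range(2):
        for cand in candidates:
            act = list(cand)
            starts = list(rate_starts)
            if seeds:
                starts += [tuple(max(s[l], 1e-4) for l in act) for s in seeds]
            for sol in _solve_branch(spec, inputs, act, starts):
                if any(
                    np.allclose(
                        [sol.rates[l] for l in labels],
                        [f.rates[l] for l in labels],
                        atol=1e-9,
                    )
                    for f in found
                ):
                    continue
                found.append(sol)
        if found or attempt == 1:
            break
        # retry with starts seeded from a short relaxation simulation
        seeds = _relaxation_seeds(spec, inputs)
    return found


def _relaxation_seeds(spec, inputs) -> list[dict[str, float]]:
    """Short relaxation runs supplying extra root-finding starts."""
    from .simulate import Constant, StimulusProtocol, simulate

    protocol = StimulusProtocol({k: Constant(v) for k, v in inputs.items()})
    seeds = []
    try:
        traj = simulate(spec, protocol, t_end=4000.0, record_stride=200)
        seeds.append({l: float(traj.rate(l)[-1]) for l in spec.labels})
    except FloatingPointError:
        pass
    return seeds


def _solve_branch(spec, inputs, active, rate_starts):
    labels = list(spec.labels)
    silent = [l for l in labels if l not in active]

    def full_rates(m_act):
        r = {l: 0.0 for l in labels}
        for l, m in zip(active, m_act):
            r[l] = m
        return r

    def residual(m_act):
        r = full_rates(m_act)
        st = _steady_state_from_rates(spec, r)
        out = np.empty(len(active))
        for i, l in enumerate(active):
            beta = spec.populations[l].beta  # steady-state slope (= matched gain)
            # at steady state M = beta * (drive + a) holds because a* = gbar*M
            # folds back into the matched gain; express via unadapted drive:
            d = inputs.get(l, 0.0) - spec.populations[l].theta
            for k, syn in enumerate(spec.synapses):
                if syn.post == l:
                    d += syn.sign * syn.g * st.s[k]
            out[i] = m_act[i] - beta * d
        return out

    sols = []
    if not active:
        r = full_rates([])
        st = _steady_state_from_rates(spec, r)
        if all(_net_drive(spec, st, inputs, l) <= 1e-12 for l in silent):
            sols.append(_finalize(spec, inputs, r, st, active))
        return sols

    seen_rates: list[np.ndarray] = []
    for start in rate_starts:
        x0 = (
            np.asarray(start, dtype=float)
            if np.ndim(start)
            else np.full(len(active), float(start))
        )
        res = optimize.root(residual, x0, method="hybr", tol=1e-13)
        if not res.success or np.max(np.abs(residual(res.x))) > 1e-10:
            continue
        m_act = res.x
        if np.any(m_act <= 1e-12):
            continue
        if any(np.allclose(m_act, prev, atol=1e-10) for prev in seen_rates):
            continue
        seen_rates.append(m_act.copy())
        r = full_rates(m_act)
        st = _steady_state_from_rates(spec, r)
        if all(_net_drive(spec, st, inputs, l) <= 1e-9 for l in silent):
            sols.append(_finalize(spec, inputs, r, st, active))
    return sols


def _finalize(spec, inputs, rates, state, active):
    eig = _branch_eigenvalues(spec, state, rates, frozenset(active))
    stable = bool(np.max(eig.real) < -STABILITY_TOL) if eig.size else True
    return SteadyStateResult(
        rates=dict(rates),
        state=state,
        active=frozenset(active),
        eigenvalues=eig,
        stable=stable,
    )


# -- linear stability ------------------------------------------------------


def _branch_eigenvalues(
    spec: CircuitSpec,
    state: NetworkState,
    rates: Mapping[str, float],
    active: frozenset[str],
) -> np.ndarray:
    """Eigenvalues of the Jacobian restricted to the branch's smooth field.

    Dynamic components: every s; x where tau_r > 0; u where tau_f > 0; a
    where adaptation is present.  The chain rule runs through the algebraic
    rates, whose derivative on the branch is gain_j for active populations
    and 0 for silent ones.
    """
    labels = list(spec.labels)
    nsyn = len(spec.synapses)
    comps: list[tuple[str, int]] = [("s", k) for k in range(nsyn)]
    comps += [("x", k) for k, syn in enumerate(spec.synapses) if syn.tau_r > 0]
    comps += [("u", k) for k, syn in enumerate(spec.synapses) if syn.tau_f > 0]
    comps += [
        ("a", i)
        for i, l in enumerate(labels)
        if spec.populations[l].adaptation is not None
    ]
    n = len(comps)
    if n == 0:
        return np.empty(0, dtype=complex)
    index = {c: i for i, c in enumerate(comps)}

    # dM_j / d(component): through s_l (post == j) and a_j
    def dM(j_label):
        """Row vector of dM_j/dz over dynamic components."""
        row = np.zeros(n)
        if j_label not in active:
            return row
        gain = spec.populations[j_label].gain
        for l, syn in enumerate(spec.synapses):
            if syn.post == j_label:
                row[index[("s", l)]] += gain * syn.sign * syn.g
        j = labels.index(j_label)
        if ("a", j) in index:
            row[index[("a", j)]] -= gain
        return row

    dM_rows = {lbl: dM(lbl) for lbl in labels}
    J = np.zeros((n, n))
    for (kind, k), i in index.items():
        if kind == "s":
            syn = spec.synapses[k]
            m = rates[syn.pre]
            s, x, u = state.s[k], state.x[k], state.u[k]
            J[i] += u * x * dM_rows[syn.pre]
            J[i, index[("s", k)]] += -1.0 / syn.tau_s
            if ("x", k) in index:
                J[i, index[("x", k)]] += u * m
            if ("u", k) in index:
                J[i, index[("u", k)]] += x * m
        elif kind == "x":
            syn = spec.synapses[k]
            m = rates[syn.pre]
            x, u = state.x[k], state.u[k]
            J[i] += -u * x * dM_rows[syn.pre]
            J[i, index[("x", k)]] += -1.0 / syn.tau_r - u * m
            if ("u", k) in index:
                J[i, index[("u", k)]] += -x * m
        elif kind == "u":
            syn = spec.synapses[k]
            m = rates[syn.pre]
            u = state.u[k]
            J[i] += syn.U * (1.0 - u) * dM_rows[syn.pre]
            J[i, index[("u", k)]] += -1.0 / syn.tau_f - syn.U * m
        else:  # adaptation
            lbl = labels[k]
            ad = spec.populations[lbl].adaptation
            J[i] += (ad.gbar_a / ad.tau_a) * dM_rows[lbl]
            J[i, index[("a", k)]] += -1.0 / ad.tau_a
    return np.linalg.eigvals(J)


def stability_eigenvalues(
    spec: CircuitSpec, fixed_point: SteadyStateResult
) -> tuple[np.ndarray, bool]:
    """Eigenvalues of the branch-restricted Jacobian and the stable flag."""
    eig = _branch_eigenvalues(spec, fixed_point.state, fixed_point.rates, fixed_point.active)
    stable = bool(np.max(eig.real) < -STABILITY_TOL) if eig.size else True
    return eig, stable


# -- RS-LTS closed forms ---------------------------------------------------


def _require_synapse(spec: CircuitSpec, post: str, pre: str) -> SynapseParams:
    syn = spec.synapse(post, pre)
    if syn is None:
        raise ValueError(f"circuit lacks the {post}<-{pre} synapse")
    return syn


def _phi(syn: SynapseParams, m: float) -> float:
    """u*(M) * M for a facilitating synapse."""
    return steady_u(syn, m) * m


def _phi_prime(syn: SynapseParams, m: float) -> float:
    """d/dM [u*(M) M] = U[(1+2 tau_f M)(1+U tau_f M) - U tau_f M(1+tau_f M)]/(1+U tau_f M)^2."""
    a = syn.tau_f
    b = syn.U * syn.tau_f
    num = (1.0 + 2.0 * a * m) * (1.0 + b * m) - b * m * (1.0 + a * m)
    return syn.U * num / (1.0 + b * m) ** 2


def lts_threshold_input(spec: CircuitSpec, I_L: float = 0.0) -> ThresholdResult:
    """Input threshold I_R,LTS,th for LTS recruitment (RS-LTS, g_RR = 0).

    While LTS are silent, M_R = beta_R (I_R - theta_R); LTS turn on when the
    facilitated L<-R drive crosses the LTS threshold current:
    g_LR tau_s,LR u*(M_R) M_R = theta_L - I_L.  Tonic LTS input I_L lowers
    the threshold.
    """
    rr = spec.synapse("R", "R")
    if rr is not None and rr.g != 0:
        raise ValueError("closed-form LTS threshold requires g_RR = 0")
    lr = _require_synapse(spec, "L", "R")
    popR = spec.populations["R"]
    popL = spec.populations["L"]
    target = popL.theta - I_L
    if target <= 0:
        # LTS suprathreshold already at M_R = 0: they turn on with RS
        return ThresholdResult(
            input_threshold=popR.theta, rate_at_threshold=0.0, population="L"
        )
    coeff = lr.g * lr.tau_s
    # u* M -> M as M -> inf at most like M, so drive is unbounded; but for
    # tiny g_LR the root can be numerically huge -- cap the bracket.
    f = lambda m: coeff * _phi(lr, m) - target
    hi = 1.0
    while f(hi) < 0 and hi < 1e9:
        hi *= 10.0
    if f(hi) < 0:
        return ThresholdResult(
            input_threshold=math.inf, rate_at_threshold=math.inf,
            population="L", attained=False,
        )
    m_th = optimize.brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14)
    return ThresholdResult(
        input_threshold=popR.theta + m_th / popR.beta,
        rate_at_threshold=m_th,
        population="L",
    )


def rs_gain_at_lts_threshold(spec: CircuitSpec, I_L: float = 0.0) -> float:
    """Slope dM_R/dI_R just above the LTS recruitment threshold.

    For small M_L the depressing R<-L synapse is undepressed
    (s_RL ~ U tau_s M_L), giving

        dM_R/dI_R = beta_R / (1 + beta_R beta_L g_RL U_RL tau_s,RL
                               * g_LR tau_s,LR * d[u* M]/dM |_th),

    which scales like 1/g_RL for large g_RL and is independent of tau_r,RL.
    """
    popR = spec.populations["R"]
    popL = spec.populations["L"]
    rl = spec.synapse("R", "L")
    if rl is None or rl.g == 0:
        return popR.beta
    lr = _require_synapse(spec, "L", "R")
    th = lts_threshold_input(spec, I_L=I_L)
    if not th.attained:
        return popR.beta
    slope_phi = _phi_prime(lr, th.rate_at_threshold)
    loop = (
        popR.beta * popL.beta * rl.g * rl.U * rl.tau_s * lr.g * lr.tau_s * slope_phi
    )
    return popR.beta / (1.0 + loop)


# -- RS-FS closed form -----------------------------------------------------


def fs_max_rate(spec: CircuitSpec, I_F: float) -> float:
    """Limiting FS rate M_F,max for large I_R in an RS-FS circuit.

    The depressing F<-R drive saturates at g_FR tau_s,FR / tau_r,FR, leaving
    the scalar implicit equation

        M_F = beta_F [ I_F + g_FR tau_s,FR/tau_r,FR
                       - g_FF s*_FF(M_F) - theta_F ]_+ .
    """
    fr = _require_synapse(spec, "F", "R")
    if fr.tau_r == 0:
        raise ValueError("F<-R synapse must depress for a finite limit")
    ff = spec.synapse("F", "F")
    popF = spec.populations["F"]
    sat = fr.g * fr.tau_s / fr.tau_r

    def f(m):
        inhib = ff.g * steady_s(ff, m) if ff is not None else 0.0
        return m - popF.beta * max(I_F + sat - inhib - popF.theta, 0.0)

    hi = max(1.0, 2.0 * popF.beta * (I_F + sat))
    if f(hi) < 0:
        raise RuntimeError("failed to bracket M_F,max")
    if f(0.0) == 0.0:
        return 0.0
    return optimize.brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14)


# -- LTS recruitment delay -------------------------------------------------


def delay_time_closed_form(
    spec: CircuitSpec, I_R: float, I_L: float = 0.0, psc_rise: bool = True
) -> float:
    """Delay from step onset to LTS recruitment (RS-LTS, g_RR = 0).

    During the delay M_R = beta_R (I_R - theta_R) is constant and u_LR
    relaxes from U toward u*(M_R) with time constant
    tau_eff = 1/(1/tau_f + U M_R); LTS fire when the facilitating drive
    g_LR s_LR crosses theta_L - I_L.  With ``psc_rise=False`` the
    postsynaptic current is taken quasi-steady (s = tau_s u M_R), giving
    the classic logarithmic formula

        t_delay = tau_eff * ln[(u* - U)/(u* - u_th)],
        u_th = (theta_L - I_L)/(g_LR tau_s,LR M_R).

    By default the few-ms rise of s itself is also resolved (the (u, s)
    subsystem is linear, so s(t) is available in closed form and the
    crossing is found by bracketed root-finding); the two versions agree
    for long delays, but only the resolved one tracks simulations when the
    delay is comparable to tau_s.  Returns +inf when the facilitated drive
    never reaches threshold (input at or below the recruitment threshold).
    """
    lr = _require_synapse(spec, "L", "R")
    popR = spec.populations["R"]
    popL = spec.populations["L"]
    m_r = popR.beta * max(I_R - popR.theta, 0.0)
    if m_r <= 0:
        return math.inf
    target = popL.theta - I_L
    if target <= 0:
        return 0.0
    u_th = target / (lr.g * lr.tau_s * m_r)
    u_star = steady_u(lr, m_r)
    if u_star <= u_th:
        return math.inf
    tau_eff = 1.0 / (1.0 / lr.tau_f + lr.U * m_r) if lr.tau_f > 0 else 0.0
    if u_th <= lr.U:
        t_u = 0.0
    else:
        t_u = tau_eff * math.log((u_star - lr.U) / (u_star - u_th))
    if not psc_rise:
        return t_u

    # s(t) = M_R int_0^t u(t') exp(-(t-t')/tau_s) dt' with
    # u(t') = u* + (U - u*) exp(-t'/tau_eff)
    tau_s = lr.tau_s

    def drive(t):
        part = u_star * tau_s * (1.0 - math.exp(-t / tau_s))
        if tau_eff > 0 and abs(1.0 / tau_s - 1.0 / tau_eff) > 1e-12:
            part += (lr.U - u_star) * (
                math.exp(-t / tau_eff) - math.exp(-t / tau_s)
            ) / (1.0 / tau_s - 1.0 / tau_eff)
        elif tau_eff > 0:  # degenerate tau_eff == tau_s
            part += (lr.U - u_star) * t * math.exp(-t / tau_s)
        return lr.g * m_r * part - target

    hi = t_u + 20.0 * tau_s
    while drive(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            return math.inf
    return float(optimize.brentq(drive, 0.0, hi, xtol=1e-10, rtol=1e-12))


# -- RS-to-RS bistability --------------------------------------------------


@dataclass
class RRBistabilityResult:
    fixed_points: dict[float, list[SteadyStateResult]]  # keyed by I_R
    bistable_inputs: list[float]  # I_R values with >= 2 stable fixed points
    M_R_c: float | None  # minimum RS rate on the active branch, if a gap exists


def detect_rr_bistability(
    spec: CircuitSpec, I_R_values: Sequence[float]
) -> RRBistabilityResult:
    """Scan fixed points over I_R to expose the g_RR-induced forbidden band.

    With strong recurrent RS excitation the active-RS branch exists only
    above a critical rate M_R,c; below it the only rest state is silence,
    and for a range of inputs both coexist (bistability).
    """
    fps: dict[float, list[SteadyStateResult]] = {}
    bistable = []
    active_rates = []
    for i_r in I_R_values:
        sols = solve_fixed_point(spec, {"R": i_r})
        fps[i_r] = sols
        stable = [s for s in sols if s.stable]
        if len(stable) >= 2:
            bistable.append(i_r)
        for s in stable:
            if s.rates["R"] > 0:
                active_rates.append(s.rates["R"])
    m_r_c = min(active_rates) if (bistable and active_rates) else None
    return RRBistabilityResult(
        fixed_points=fps, bistable_inputs=bistable, M_R_c=m_r_c
    )


# -- invariants helper -----------------------------------------------------


def fixed_point_residual(
    spec: CircuitSpec, fp: SteadyStateResult, inputs: Mapping[str, float]
) -> float:
    """Max-norm of the vector field at a reported fixed point."""
    rates = population_rates(spec, fp.state, dict(inputs))
    d = derivatives(spec, fp.state, rates)
    parts = [d.s, d.x, d.u, d.a]
    rate_err = max(abs(rates[l] - fp.rates[l]) for l in spec.labels)
    return max(rate_err, max(float(np.max(np.abs(p))) if p.size else 0.0 for p in parts))
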