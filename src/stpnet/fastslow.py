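"""Fast-slow analysis of the reduced RS-LTS-FS circuit.

The reduced circuit (see :func:`stpnet.circuit.reduced_circuit`) keeps only
the L<-R, R<-L, F<-R and L<-F connections with tau_r = 0 everywhere, so the
facilitation u of the L<-R synapse (time constant tau_f = 670 ms) is the
single slow variable.  Treating u as a frozen parameter, every s variable
equilibrates on the few-ms tau_s scale (s_ij = tau_s,ij u_ij M_j) and the
fast subsystem settles onto one of two stable branches:

* upper branch -- LTS silent, FS active, M_R^ = beta_R (I_R - theta_R)
  independent of u; it exists for u below the saddle-node value u+ where
  the LTS-onset condition is met;
* lower branch -- FS silent, LTS active, (M_R, M_L) solve a linear 2x2
  system; M_R^-(u) decreases with u and the branch exists for u above the
  saddle-node value u- where the FS-onset condition is met.

In the limit tau_f -> inf, U -> 0 with C = U tau_f fixed, the slow flow is
du/dt = [-u + C M_R (1-u)]/tau_f, whose nullcline is u = C M_R/(1 + C M_R);
u grows below the nullcline and shrinks above it.  Slow relaxation
oscillations (jumping between the branches at u+ and u-) occur iff

1. u+ > u-                         (fast-subsystem bistability),
2. C M_R^/(1 + C M_R^) > u+        (nullcline misses the upper branch, so
                                    u keeps growing there), and
3. u- > C M_os/(1 + C M_os)        (nullcline misses the lower branch over
                                    [u-, u+], so u keeps shrinking there;
                                    M_os is the lower-branch rate at u-).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .circuit import CircuitSpec, rectify

__all__ = [
    "ReducedConstants",
    "FastSlowResult",
    "slow_nullcline",
    "fast_branches",
    "saddle_points",
    "oscillation_conditions",
    "reduced_phase_diagram",
    "oscillatory_band",
]


@dataclass(frozen=True)
class ReducedConstants:
    """Lumped couplings of the reduced circuit (current per unit rate)."""

    beta_R: float
    beta_L: float
    beta_F: float
    theta_R: float
    theta_L: float
    theta_F: float
    A_RL: float  # g_RL tau_s,RL U_RL : LTS -> RS inhibition
    B_LR: float  # g_LR tau_s,LR      : RS -> LTS excitation per unit u
    D_FR: float  # g_FR tau_s,FR U_FR : RS -> FS excitation
    E_LF: float  # g_LF tau_s,LF U_LF : FS -> LTS inhibition
    C: float  # U_LR tau_f,LR, ms -- slow-variable lumped constant

    @classmethod
    def from_spec(cls, spec: CircuitSpec) -> "ReducedConstants":
        required = {("L", "R"), ("R", "L"), ("F", "R"), ("L", "F")}
        keys = {s.key for s in spec.synapses}
        if keys != required:
            raise ValueError(
                "reduced circuit must contain exactly the L<-R, R<-L, F<-R, "
                f"L<-F synapses; got {sorted(keys)}"
            )
        for syn in spec.synapses:
            if syn.tau_r != 0:
                raise ValueError("reduced circuit requires tau_r = 0 everywhere")
            if syn.key != ("L", "R") and syn.tau_f != 0:
                raise ValueError("only the L<-R synapse may facilitate")
        lr = spec.synapse("L", "R")
        rl = spec.synapse("R", "L")
        fr = spec.synapse("F", "R")
        lf = spec.synapse("L", "F")
        p = spec.populations
        return cls(
            beta_R=p["R"].beta, beta_L=p["L"].beta, beta_F=p["F"].beta,
            theta_R=p["R"].theta, theta_L=p["L"].theta, theta_F=p["F"].theta,
            A_RL=rl.g * rl.tau_s * rl.U,
            B_LR=lr.g * lr.tau_s,
            D_FR=fr.g * fr.tau_s * fr.U,
            E_LF=lf.g * lf.tau_s * lf.U,
            C=lr.U * lr.tau_f,
        )


@dataclass
class FastSlowResult:
    C: float
    u_plus: float | None
    u_minus: float | None
    M_R_upper: float  # upper-branch RS rate (constant in u)
    M_F_upper: float  # upper-branch FS rate
    bistable: bool
    upper_no_intersect: bool
    lower_no_intersect: bool
    oscillatory: bool
    label: str  # predicted regime


def slow_nullcline(C: float, M_R: float) -> float:
    """u = C M_R / (1 + C M_R): stationary u of the limiting slow flow."""
    if M_R < 0:
        raise ValueError("M_R must be non-negative")
    return C * M_R / (1.0 + C * M_R)


def _upper_branch(k: ReducedConstants, I_R: float, I_F: float):
    """(M_R, M_F) with LTS silent; M_R is independent of u."""
    m_r = k.beta_R * rectify(I_R - k.theta_R)
    m_f = k.beta_F * rectify(I_F + k.D_FR * m_r - k.theta_F)
    return m_r, m_f


def _lower_branch_rates(k: ReducedConstants, I_R: float, u: float):
    """(M_R, M_L) with FS silent, solving the linear 2x2 system at frozen u."""
    denom = 1.0 + k.beta_R * k.beta_L * k.A_RL * k.B_LR * u
    m_r = (k.beta_R * (I_R - k.theta_R) + k.beta_R * k.beta_L * k.A_RL * k.theta_L) / denom
    m_l = k.beta_L * (k.B_LR * u * m_r - k.theta_L)
    return m_r, m_l


def fast_branches(
    spec: CircuitSpec, I_R: float, I_F: float, u: float
) -> dict[str, dict[str, float]]:
    """Fast-subsystem equilibria at frozen u; present keys: 'upper', 'lower'.

    Existence of each branch is checked by the sign conditions on the
    assumed-silent population (LTS on the upper branch, FS on the lower).
    """
    k = ReducedConstants.from_spec(spec)
    out: dict[str, dict[str, float]] = {}
    m_r_up, m_f_up = _upper_branch(k, I_R, I_F)
    l_drive = k.B_LR * u * m_r_up - k.E_LF * m_f_up - k.theta_L
    if l_drive <= 0:
        out["upper"] = {"M_R": m_r_up, "M_L": 0.0, "M_F": m_f_up}
    m_r_lo, m_l_lo = _lower_branch_rates(k, I_R, u)
    f_drive = I_F + k.D_FR * m_r_lo - k.theta_F
    if m_l_lo > 0 and m_r_lo > 0 and f_drive <= 0:
        out["lower"] = {"M_R": m_r_lo, "M_L": m_l_lo, "M_F": 0.0}
    return out


def saddle_points(
    spec: CircuitSpec, I_R: float, I_F: float
) -> tuple[float | None, float | None]:
    """Saddle-node values (u_plus, u_minus) of the two branches.

    u_plus: LTS-onset condition (M_L = 0+) on the upper branch,
        u+ = (theta_L + E_LF M_F^) / (B_LR M_R^).
    u_minus: FS-onset condition (M_F = 0+) on the lower branch, obtained by
        inverting M_R^-(u) at the FS-onset rate M_os = (theta_F - I_F)/D_FR.
    None marks a branch that is absent for every u (the required onset rate
    is negative).
    """
    k = ReducedConstants.from_spec(spec)
    m_r_up, m_f_up = _upper_branch(k, I_R, I_F)
    u_plus = None
    if m_r_up > 0:
        u_plus = (k.theta_L + k.E_LF * m_f_up) / (k.B_LR * m_r_up)
    u_minus = None
    if I_F < k.theta_F:
        m_os = (k.theta_F - I_F) / k.D_FR
        num = k.beta_R * (I_R - k.theta_R) + k.beta_R * k.beta_L * k.A_RL * k.theta_L
        if m_os > 0 and num > m_os:
            u_minus = (num / m_os - 1.0) / (k.beta_R * k.beta_L * k.A_RL * k.B_LR)
            # lower branch must carry positive LTS rate at its knee
            _, m_l = _lower_branch_rates(k, I_R, u_minus)
            if m_l <= 0:
                u_minus = None
    return u_plus, u_minus


def oscillation_conditions(
    spec: CircuitSpec, I_R: float, I_F: float
) -> FastSlowResult:
    """Evaluate the three slow-oscillation conditions at one input point."""
    k = ReducedConstants.from_spec(spec)
    m_r_up, m_f_up = _upper_branch(k, I_R, I_F)
    u_plus, u_minus = saddle_points(spec, I_R, I_F)

    bistable = u_plus is not None and u_minus is not None and u_plus > u_minus
    upper_ok = False
    if u_plus is not None:
        upper_ok = slow_nullcline(k.C, m_r_up) > u_plus
    lower_ok = False
    if u_minus is not None:
        m_os = _lower_branch_rates(k, I_R, u_minus)[0]
        lower_ok = u_minus > slow_nullcline(k.C, m_os)
    osc = bistable and upper_ok and lower_ok

    label = _predict_label(k, I_R, I_F, u_plus, u_minus, m_r_up, m_f_up, osc)
    return FastSlowResult(
        C=k.C, u_plus=u_plus, u_minus=u_minus,
        M_R_upper=m_r_up, M_F_upper=m_f_up,
        bistable=bistable, upper_no_intersect=upper_ok,
        lower_no_intersect=lower_ok, oscillatory=osc, label=label,
    )


def _predict_label(k, I_R, I_F, u_plus, u_minus, m_r_up, m_f_up, osc) -> str:
    if m_r_up <= 0:
        return "MR=0"
    if osc:
        return "osc"
    # rest on the upper branch: nullcline intersects it within existence range
    u_rest_up = slow_nullcline(k.C, m_r_up)
    if u_plus is None or u_rest_up <= u_plus:
        if m_f_up > 0:
            # LTS silent; are they silent because of FS or genuinely subthreshold?
            return "ML=0"
        return "ML=MF=0"
    # rest on the lower branch: solve u = nullcline(M_R^-(u)) on [u_minus, 1]
    u_rest_lo = _lower_branch_rest(k, I_R)
    if u_rest_lo is not None:
        lo_floor = u_minus if u_minus is not None else 0.0
        m_r, m_l = _lower_branch_rates(k, I_R, u_rest_lo)
        if u_rest_lo >= lo_floor and m_l > 0:
            if I_F + k.D_FR * m_r - k.theta_F <= 0:
                return "MF=0"
    return "ML>0,MF>0"


def _lower_branch_rest(k: ReducedConstants, I_R: float) -> float | None:
    """Root of u - nullcline(M_R^-(u)) on (0, 1), if any."""
    from scipy.optimize import brentq

    def f(u):
        m_r, _ = _lower_branch_rates(k, I_R, u)
        return u - slow_nullcline(k.C, max(m_r, 0.0))

    lo, hi = 1e-9, 1.0
    if f(lo) > 0 or f(hi) < 0:
        return None
    return float(brentq(f, lo, hi, xtol=1e-12))


def reduced_phase_diagram(
    spec: CircuitSpec,
    I_R_values: Sequence[float],
    I_F_values: Sequence[float],
) -> pd.DataFrame:
    """Closed-form regime prediction on an (I_R, I_F) grid."""
    rows = []
    for i_r in I_R_values:
        for i_f in I_F_values:
            res = oscillation_conditions(spec, float(i_r), float(i_f))
            rows.append(
                {
                    "I_R": float(i_r),
                    "I_F": float(i_f),
                    "label": res.label,
                    "u_plus": res.u_plus if res.u_plus is not None else np.nan,
                    "u_minus": res.u_minus if res.u_minus is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def oscillatory_band(
    spec: CircuitSpec,
    I_R: float,
    I_F_bracket: tuple[float, float] = (0.0, 0.4),
    tol: float = 1e-6,
    scan_points: int = 200,
) -> tuple[float, float] | None:
    """I_F interval of predicted oscillation at fixed I_R, by bisection.

    Closed-form evaluation makes a dense scan plus edge bisection cheap;
    returns None when no scanned point is oscillatory.
    """

    def osc(i_f: float) -> bool:
        return oscillation_conditions(spec, I_R, float(i_f)).oscillatory

    grid = np.linspace(*I_F_bracket, scan_points)
    flags = [osc(g) for g in grid]
    if not any(flags):
        return None
    first = int(np.argmax(flags))
    last = len(flags) - 1 - int(np.argmax(flags[::-1]))

    def bisect(a, b, rising):
        while b - a > tol:
            m = 0.5 * (a + b)
            if osc(m) == rising:
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
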