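"""Domain types and right-hand side of the cortical rate model.

The circuit couples up to three neuronal populations -- regular-spiking
pyramidal cells (R), low-threshold-spiking somatostatin interneurons (L)
and fast-spiking parvalbumin interneurons (F) -- through chemical synapses
with Tsodyks-Markram short-term plasticity.  Each synapse carries three
state variables: the open-channel fraction ``s``, the available-vesicle
fraction ``x`` (depression) and the running utilization ``u``
(facilitation).  Population firing rates are algebraic, rectified-linear
functions of the synaptic currents:

    M_i = beta_i * [ I_i + sum_j sign_j g_ij s_ij - a_i - theta_i ]_+

with time in ms, currents in nA and rates in ms^-1 (multiply by 1000 for
Hz).  ``a_i`` is an optional spike-frequency-adaptation current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "EXCITATORY_LABELS",
    "PopulationParams",
    "AdaptationParams",
    "SynapseParams",
    "CircuitSpec",
    "NetworkState",
    "rectify",
    "population_rates",
    "derivatives",
    "steady_u",
    "steady_x",
    "steady_s",
    "reference_circuit",
    "reduced_circuit",
]

#: population labels whose outgoing synapses are excitatory (sign +1)
EXCITATORY_LABELS = frozenset({"R"})


def rectify(v: float) -> float:
    """Linear-threshold function [v]_+ : v for v >= 0, else 0."""
    return v if v >= 0.0 else 0.0


@dataclass(frozen=True)
class AdaptationParams:
    """Spike-frequency adaptation of one population.

    The adaptation current obeys  da/dt = (-a + gbar_a * M) / tau_a  and is
    subtracted from the population's input.  ``beta_tilde`` is the unadapted
    gain; the matched-gain constraint beta = beta_tilde/(1 + beta_tilde*gbar_a)
    keeps the steady-state f-I slope identical to the model without
    adaptation.
    """

    tau_a: float  # ms
    gbar_a: float  # nA per (ms^-1)
    beta_tilde: float  # ms^-1 nA^-1

    def __post_init__(self) -> None:
        if not self.tau_a > 0:
            raise ValueError("tau_a must be positive")
        if self.gbar_a < 0:
            raise ValueError("gbar_a must be non-negative")
        if not self.beta_tilde > 0:
            raise ValueError("beta_tilde must be positive")

    @property
    def steady_gain(self) -> float:
        """Effective steady-state gain beta_tilde/(1+beta_tilde*gbar_a)."""
        return self.beta_tilde / (1.0 + self.beta_tilde * self.gbar_a)

    @classmethod
    def matched(cls, beta: float, gbar_a: float, tau_a: float) -> "AdaptationParams":
        """Build parameters whose steady-state gain equals ``beta``.

        Solves beta = beta_tilde/(1+beta_tilde*gbar_a) for beta_tilde; requires
        beta*gbar_a < 1.
        """
        denom = 1.0 - beta * gbar_a
        if denom <= 0:
            raise ValueError("matched gain requires beta*gbar_a < 1")
        return cls(tau_a=tau_a, gbar_a=gbar_a, beta_tilde=beta / denom)

    @classmethod
    def from_gain_reduction(
        cls, beta: float, rho: float, tau_a: float
    ) -> "AdaptationParams":
        """Build matched parameters from the gain-reduction factor.

        ``rho`` = 1 + beta_tilde*gbar_a is the factor by which the initial
        (unadapted) step response exceeds the steady-state response.
        """
        if rho < 1:
            raise ValueError("gain-reduction factor must be >= 1")
        gbar_a = (rho - 1.0) / (rho * beta)
        return cls.matched(beta=beta, gbar_a=gbar_a, tau_a=tau_a)


@dataclass(frozen=True)
class PopulationParams:
    label: str
    theta: float  # firing-threshold current, nA
    beta: float  # steady-state gain, ms^-1 nA^-1
    adaptation: AdaptationParams | None = None

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive for population {self.label!r}")
        if not math.isfinite(self.theta):
            raise ValueError(f"theta must be finite for population {self.label!r}")

    @property
    def gain(self) -> float:
        """Instantaneous gain used in the rate equation.

        beta_tilde when adaptation is present (the adaptation current then
        brings the steady-state slope back to beta), beta otherwise.
        """
        return self.adaptation.beta_tilde if self.adaptation else self.beta


@dataclass(frozen=True)
class SynapseParams:
    """One directed connection (post <- pre) with Tsodyks-Markram kinetics.

    tau_f = 0 pins u at U exactly (no facilitation); tau_r = 0 pins x at 1
    exactly (no depression).  The sign of the synaptic current is fixed by
    the presynaptic population type: +1 for excitatory (R), -1 for the
    inhibitory interneurons (L, F).
    """

    pre: str
    post: str
    g: float  # efficacy coefficient (g*s is a current in nA)
    U: float  # baseline release probability
    tau_s: float  # ms, postsynaptic current decay
    tau_f: float = 0.0  # ms, facilitation recovery (0 => none)
    tau_r: float = 0.0  # ms, depression recovery (0 => none)

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("g must be non-negative")
        if not 0.0 < self.U <= 1.0:
            raise ValueError("U must lie in (0, 1]")
        if not self.tau_s > 0:
            raise ValueError("tau_s must be positive")
        if self.tau_f < 0 or self.tau_r < 0:
            raise ValueError("tau_f and tau_r must be non-negative")

    @property
    def sign(self) -> int:
        return +1 if self.pre in EXCITATORY_LABELS else -1

    @property
    def key(self) -> tuple[str, str]:
        return (self.post, self.pre)


@dataclass(frozen=True)
class CircuitSpec:
    """Populations plus a directed synapse map (absent pair => no connection)."""

    populations: dict[str, PopulationParams]
    synapses: tuple[SynapseParams, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for syn in self.synapses:
            if syn.key in seen:
                raise ValueError(f"duplicate synapse {syn.post}<-{syn.pre}")
            seen.add(syn.key)
            for lbl in (syn.pre, syn.post):
                if lbl not in self.populations:
                    raise ValueError(f"synapse endpoint {lbl!r} not declared")
        for lbl, pop in self.populations.items():
            if pop.label != lbl:
                raise ValueError(f"population key {lbl!r} != label {pop.label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.populations)

    def synapse(self, post: str, pre: str) -> SynapseParams | None:
        for syn in self.synapses:
            if syn.post == post and syn.pre == pre:
                return syn
        return None

    def with_synapse(self, post: str, pre: str, **changes) -> "CircuitSpec":
        """Return a copy with one synapse's parameters replaced."""
        syns = []
        found = False
        for syn in self.synapses:
            if syn.post == post and syn.pre == pre:
                syns.append(replace(syn, **changes))
                found = True
            else:
                syns.append(syn)
        if not found:
            raise KeyError(f"no synapse {post}<-{pre}")
        return CircuitSpec(populations=dict(self.populations), synapses=tuple(syns))

    def without_synapse(self, post: str, pre: str) -> "CircuitSpec":
        syns = tuple(s for s in self.synapses if not (s.post == post and s.pre == pre))
        return CircuitSpec(populations=dict(self.populations), synapses=syns)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        pops = {}
        for lbl, p in self.populations.items():
            d: dict = {"theta": p.theta, "beta": p.beta}
            if p.adaptation:
                d["adaptation"] = {
                    "tau_a": p.adaptation.tau_a,
                    "gbar_a": p.adaptation.gbar_a,
                    "beta_tilde": p.adaptation.beta_tilde,
                }
            pops[lbl] = d
        syns = [
            {
                "pre": s.pre,
                "post": s.post,
                "g": s.g,
                "U": s.U,
                "tau_s": s.tau_s,
                "tau_f": s.tau_f,
                "tau_r": s.tau_r,
            }
            for s in self.synapses
        ]
        return {"populations": pops, "synapses": syns}

    @classmethod
    def from_dict(cls, data: Mapping) -> "CircuitSpec":
        pops = {}
        for lbl, d in data["populations"].items():
            adapt = None
            if d.get("adaptation"):
                adapt = AdaptationParams(**d["adaptation"])
            pops[lbl] = PopulationParams(
                label=lbl, theta=d["theta"], beta=d["beta"], adaptation=adapt
            )
        syns = tuple(SynapseParams(**s) for s in data["synapses"])
        return cls(populations=pops, synapses=syns)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CircuitSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class NetworkState:
    """All synaptic state variables and adaptation currents at one instant.

    Arrays are aligned with ``spec.synapses`` (s, x, u) and ``spec.labels``
    (a).
    """

    s: np.ndarray
    x: np.ndarray
    u: np.ndarray
    a: np.ndarray

    def copy(self) -> "NetworkState":
        return NetworkState(self.s.copy(), self.x.copy(), self.u.copy(), self.a.copy())

    @classmethod
    def rested(cls, spec: CircuitSpec) -> "NetworkState":
        """Long-rested default: s=0, x=1, u=U, a=0."""
        n = len(spec.synapses)
        return cls(
            s=np.zeros(n),
            x=np.ones(n),
            u=np.array([syn.U for syn in spec.synapses]),
            a=np.zeros(len(spec.populations)),
        )

    def validate(self, spec: CircuitSpec) -> None:
        if np.any(self.s < 0) or np.any(self.a < 0):
            raise ValueError("negative state components")
        if np.any(self.x < 0) or np.any(self.x > 1):
            raise ValueError("x outside [0, 1]")
        for k, syn in enumerate(spec.synapses):
            if not (syn.U - 1e-12 <= self.u[k] <= 1 + 1e-12):
                raise ValueError(f"u outside [U, 1] for synapse {syn.post}<-{syn.pre}")


# -- algebraic rates and vector field -------------------------------------


def population_rates(
    spec: CircuitSpec, state: NetworkState, inputs: Mapping[str, float]
) -> dict[str, float]:
    """Rates M_i = beta_i * [I_i + sum_j sign*g_ij*s_ij - a_i - theta_i]_+.

    Purely algebraic in (s, a); no self-reference through M.
    """
    for lbl in inputs:
        if lbl not in spec.populations:
            raise KeyError(f"unknown population label {lbl!r} in inputs")
    labels = spec.labels
    drive = {lbl: inputs.get(lbl, 0.0) - spec.populations[lbl].theta for lbl in labels}
    for k, syn in enumerate(spec.synapses):
        drive[syn.post] += syn.sign * syn.g * state.s[k]
    for i, lbl in enumerate(labels):
        drive[lbl] -= state.a[i]
    return {
        lbl: spec.populations[lbl].gain * rectify(drive[lbl]) for lbl in labels
    }


def derivatives(
    spec: CircuitSpec, state: NetworkState, rates: Mapping[str, float]
) -> NetworkState:
    """Time derivatives of (s, x, u, a) given the algebraic rates.

    ds/dt = -s/tau_s + u*x*M_pre
    dx/dt = (1-x)/tau_r - u*x*M_pre      (x held at 1 when tau_r = 0)
    du/dt = (U-u)/tau_f + U*(1-u)*M_pre  (u held at U when tau_f = 0)
    da/dt = (-a + gbar_a*M_i)/tau_a      (a held at 0 without adaptation)
    """
    if np.any(state.s < 0) or np.any(state.x < 0) or np.any(state.u < 0):
        raise ValueError("negative state components")
    n = len(spec.synapses)
    ds = np.zeros(n)
    dx = np.zeros(n)
    du = np.zeros(n)
    for k, syn in enumerate(spec.synapses):
        m = rates[syn.pre]
        s, x, u = state.s[k], state.x[k], state.u[k]
        ds[k] = -s / syn.tau_s + u * x * m
        if syn.tau_r > 0:
            dx[k] = (1.0 - x) / syn.tau_r - u * x * m
        if syn.tau_f > 0:
            du[k] = (syn.U - u) / syn.tau_f + syn.U * (1.0 - u) * m
    da = np.zeros(len(spec.populations))
    for i, lbl in enumerate(spec.labels):
        ad = spec.populations[lbl].adaptation
        if ad is not None:
            da[i] = (-state.a[i] + ad.gbar_a * rates[lbl]) / ad.tau_a
    return NetworkState(s=ds, x=dx, u=du, a=da)


# -- steady-state closed forms ---------------------------------------------


def steady_u(syn: SynapseParams, m: float) -> float:
    """u* = U(1 + tau_f M)/(1 + U tau_f M); u* = U when tau_f = 0."""
    if syn.tau_f == 0.0:
        return syn.U
    return syn.U * (1.0 + syn.tau_f * m) / (1.0 + syn.U * syn.tau_f * m)


def steady_x(syn: SynapseParams, m: float) -> float:
    """x* = 1/(1 + tau_r u* M); x* = 1 when tau_r = 0."""
    if syn.tau_r == 0.0:
        return 1.0
    return 1.0 / (1.0 + syn.tau_r * steady_u(syn, m) * m)


def steady_s(syn: SynapseParams, m: float) -> float:
    """s* = tau_s u* x* M for a constant presynaptic rate M."""
    return syn.tau_s * steady_u(syn, m) * steady_x(syn, m) * m


# -- reference circuits ----------------------------------------------------

_POPULATION_TABLE = {
    # label: (theta nA, beta ms^-1 nA^-1)
    "R": (0.1, 0.11),
    "L": (0.05, 0.32),
    "F": (0.28, 0.35),
}

_SYNAPSE_TABLE = [
    # (post, pre, tau_s, tau_f, tau_r, U, g)
    ("R", "R", 2.0, 0.0, 463.0, 0.21, 5.0),
    ("R", "L", 6.3, 0.0, 1250.0, 0.30, 35.0),
    ("L", "R", 2.0, 670.0, 0.0, 0.09, 7.0),
    ("R", "F", 2.0, 0.0, 875.0, 0.14, 38.0),
    ("F", "R", 2.0, 0.0, 227.0, 0.30, 18.0),
    ("F", "L", 2.0, 0.0, 400.0, 0.30, 5.0),
    ("L", "F", 2.0, 0.0, 400.0, 0.30, 10.0),
    ("F", "F", 2.0, 0.0, 400.0, 0.30, 20.0),
]

#: default adaptation settings used by ``reference_circuit(adaptation=True)``
DEFAULT_ADAPTATION = {"rho": 2.0, "tau_a": 100.0}


def reference_circuit(
    g_rr: bool = True,
    adaptation: bool = False,
    adaptation_params: Mapping[str, Mapping[str, float]] | None = None,
) -> CircuitSpec:
    """The reference RS-LTS-FS circuit.

    Parameters
    ----------
    g_rr
        If False, the RS<-RS efficacy is set to 0 (all other parameters
        unchanged).
    adaptation
        Add a matched-gain adaptation current to every population: the
        steady-state f-I slope stays equal to beta while the initial step
        response is stronger by the gain-reduction factor rho.
    adaptation_params
        Optional per-label override ``{"R": {"rho": ..., "tau_a": ...}}``.
    """
    pops = {}
    for lbl, (theta, beta) in _POPULATION_TABLE.items():
        adapt = None
        if adaptation:
            cfg = dict(DEFAULT_ADAPTATION)
            if adaptation_params and lbl in adaptation_params:
                cfg.update(adaptation_params[lbl])
            adapt = AdaptationParams.from_gain_reduction(
                beta=beta, rho=cfg["rho"], tau_a=cfg["tau_a"]
            )
        pops[lbl] = PopulationParams(label=lbl, theta=theta, beta=beta, adaptation=adapt)
    syns = []
    for post, pre, tau_s, tau_f, tau_r, U, g in _SYNAPSE_TABLE:
        if post == "R" and pre == "R" and not g_rr:
            g = 0.0
        syns.append(
            SynapseParams(pre=pre, post=post, g=g, U=U, tau_s=tau_s, tau_f=tau_f, tau_r=tau_r)
        )
    return CircuitSpec(populations=pops, synapses=tuple(syns))


def rs_lts_circuit(g_rl: float = 35.0, g_lr: float = 7.5, g_rr: float = 0.0) -> CircuitSpec:
    """Two-population RS-LTS subcircuit (facilitating L<-R, depressing R<-L)."""
    pops = {
        lbl: PopulationParams(label=lbl, theta=t, beta=b)
        for lbl, (t, b) in _POPULATION_TABLE.items()
        if lbl in ("R", "L")
    }
    syns = [
        SynapseParams(pre="R", post="L", g=g_lr, U=0.09, tau_s=2.0, tau_f=670.0, tau_r=0.0),
        SynapseParams(pre="L", post="R", g=g_rl, U=0.30, tau_s=6.3, tau_f=0.0, tau_r=1250.0),
    ]
    if g_rr > 0:
        syns.append(
            SynapseParams(pre="R", post="R", g=g_rr, U=0.21, tau_s=2.0, tau_f=0.0, tau_r=463.0)
        )
    return CircuitSpec(populations=pops, synapses=tuple(syns))


def rs_fs_circuit(
    g_rr: float = 20.0, g_fr: float = 25.0, g_rf: float = 50.0, g_ff: float = 5.0
) -> CircuitSpec:
    """Two-population RS-FS subcircuit with mutually coupled FS cells."""
    pops = {
        lbl: PopulationParams(label=lbl, theta=t, beta=b)
        for lbl, (t, b) in _POPULATION_TABLE.items()
        if lbl in ("R", "F")
    }
    syns = []
    if g_rr > 0:
        syns.append(
            SynapseParams(pre="R", post="R", g=g_rr, U=0.21, tau_s=2.0, tau_f=0.0, tau_r=463.0)
        )
    syns += [
        SynapseParams(pre="R", post="F", g=g_fr, U=0.30, tau_s=2.0, tau_f=0.0, tau_r=227.0),
        SynapseParams(pre="F", post="R", g=g_rf, U=0.14, tau_s=2.0, tau_f=0.0, tau_r=875.0),
    ]
    if g_ff > 0:
        syns.append(
            SynapseParams(pre="F", post="F", g=g_ff, U=0.30, tau_s=2.0, tau_f=0.0, tau_r=400.0)
        )
    return CircuitSpec(populations=pops, synapses=tuple(syns))


def reduced_circuit(
    g_lr: float = 7.5, g_rl: float = 35.0, g_fr: float = 9.3, g_lf: float = 8.0
) -> CircuitSpec:
    """Reduced RS-LTS-FS circuit for fast-slow analysis.

    Only the L<-R, R<-L, F<-R and L<-F connections are kept, with tau_r = 0
    everywhere, so the single slow variable is the facilitation u of the
    L<-R synapse (tau_f = 670 ms); every other variable relaxes on the few-ms
    tau_s scale.
    """
    pops = {
        lbl: PopulationParams(label=lbl, theta=t, beta=b)
        for lbl, (t, b) in _POPULATION_TABLE.items()
    }
    syns = (
        SynapseParams(pre="R", post="L", g=g_lr, U=0.09, tau_s=2.0, tau_f=670.0, tau_r=0.0),
        SynapseParams(pre="L", post="R", g=g_rl, U=0.30, tau_s=6.3, tau_f=0.0, tau_r=0.0),
        SynapseParams(pre="R", post="F", g=g_fr, U=0.30, tau_s=2.0, tau_f=0.0, tau_r=0.0),
        SynapseParams(pre="F", post="L", g=g_lf, U=0.30, tau_s=2.0, tau_f=0.0, tau_r=0.0),
    )
    return CircuitSpec(populations=pops, synapses=syns)
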