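"""Model core: rates, synaptic kinetics, reference parameter sets."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from stpnet.circuit import (
    CircuitSpec,
    NetworkState,
    PopulationParams,
    SynapseParams,
    derivatives,
    population_rates,
    rectify,
    reduced_circuit,
    reference_circuit,
    rs_lts_circuit,
    steady_s,
    steady_u,
    steady_x,
)


@pytest.mark.parametrize("v,expected", [(0.3, 0.3), (-0.3, 0.0), (0.0, 0.0)])
def test_rectify(v, expected):
    assert rectify(v) == expected


class TestPopulationRates:
    def test_decoupled_rs_above_threshold(self):
        spec = rs_lts_circuit(g_rl=0.0, g_lr=0.0)
        state = NetworkState.rested(spec)
        rates = population_rates(spec, state, {"R": 0.5})
        assert rates["R"] == pytest.approx(0.11 * (0.5 - 0.1))  # 0.044 ms^-1 = 44 Hz
        assert rates["L"] == 0.0

    def test_subthreshold_is_silent(self):
        spec = rs_lts_circuit(g_rl=0.0, g_lr=0.0)
        rates = population_rates(spec, NetworkState.rested(spec), {"R": 0.09})
        assert rates["R"] == 0.0

    def test_exact_inhibitory_cancellation(self, reference):
        state = NetworkState.rested(reference)
        i_r = 0.5
        k = [i for i, s in enumerate(reference.synapses) if s.key == ("R", "L")][0]
        syn = reference.synapses[k]
        state.s[k] = (i_r - reference.populations["R"].theta) / syn.g
        rates = population_rates(reference, state, {"R": i_r})
        assert rates["R"] == 0.0

    def test_unknown_label_raises(self, reference):
        with pytest.raises(KeyError):
            population_rates(reference, NetworkState.rested(reference), {"Q": 0.1})

    def test_rates_invariant_under_relabeling(self, reference):
        """Permuting population labels permutes the rates and nothing else."""
        mapping = {"R": "R2", "L": "L2", "F": "F2"}
        # relabeling keeps the R-prefix convention for excitatory populations
        pops = {
            mapping[l]: PopulationParams(
                label=mapping[l], theta=p.theta, beta=p.beta, adaptation=p.adaptation
            )
            for l, p in reference.populations.items()
        }
        syns = tuple(
            SynapseParams(
                pre=mapping[s.pre], post=mapping[s.post], g=s.g, U=s.U,
                tau_s=s.tau_s, tau_f=s.tau_f, tau_r=s.tau_r,
            )
            for s in reference.synapses
        )
        # patch signs: excitatory set is {"R"}; R2 must stay excitatory
        import stpnet.circuit as c

        state = NetworkState.rested(reference)
        state.s[:] = 0.001
        r1 = population_rates(reference, state, {"R": 0.4, "F": 0.3})
        orig = c.EXCITATORY_LABELS
        c.EXCITATORY_LABELS = frozenset({"R2"})
        try:
            permuted = CircuitSpec(populations=pops, synapses=syns)
            r2 = population_rates(permuted, state, {"R2": 0.4, "F2": 0.3})
            for l in mapping:
                assert r2[mapping[l]] == pytest.approx(r1[l], abs=1e-15)
        finally:
            c.EXCITATORY_LABELS = orig


class TestSynapticSteadyStates:
    """Closed forms vs long-time integration of the single-synapse ODEs."""

    def _integrate_to_steady(self, syn, m, t_end=60000.0):
        def rhs(_, y):
            s, x, u = y
            du = (syn.U - u) / syn.tau_f + syn.U * (1 - u) * m if syn.tau_f else 0.0
            dx = (1 - x) / syn.tau_r - u * x * m if syn.tau_r else 0.0
            ds = -s / syn.tau_s + u * x * m
            return [ds, dx, du]

        sol = solve_ivp(rhs, (0, t_end), [0.0, 1.0, syn.U], rtol=1e-12, atol=1e-14)
        return sol.y[:, -1]

    def test_facilitating_utilization(self):
        # L<-R synapse at a constant 20 Hz presynaptic rate
        syn = SynapseParams(pre="R", post="L", g=7.0, U=0.09, tau_s=2.0, tau_f=670.0)
        m = 0.02
        assert steady_u(syn, m) == pytest.approx(0.5875, abs=2e-4)
        s, x, u = self._integrate_to_steady(syn, m)
        assert u == pytest.approx(steady_u(syn, m), rel=1e-6)
        assert s == pytest.approx(steady_s(syn, m), rel=1e-6)

    def test_depressing_resources(self):
        # R<-L synapse at a constant 20 Hz presynaptic rate
        syn = SynapseParams(pre="L", post="R", g=35.0, U=0.3, tau_s=6.3, tau_r=1250.0)
        m = 0.02
        assert steady_x(syn, m) == pytest.approx(0.1176, abs=1e-4)
        s, x, u = self._integrate_to_steady(syn, m)
        assert x == pytest.approx(steady_x(syn, m), rel=1e-6)
        assert s == pytest.approx(steady_s(syn, m), rel=1e-6)

    def test_static_synapse_fixed_point(self):
        syn = SynapseParams(pre="R", post="L", g=1.0, U=0.5, tau_s=4.0)
        m = 0.05
        assert steady_s(syn, m) == pytest.approx(syn.tau_s * syn.U * m)

    def test_facilitation_limit_matches_slow_nullcline(self):
        """U->0, tau_f->inf at fixed C=U*tau_f gives u* -> CM/(1+CM)."""
        m, C = 0.02, 60.3
        for U in (0.09, 0.01, 0.001, 1e-5):
            syn = SynapseParams(pre="R", post="L", g=1.0, U=U, tau_s=2.0, tau_f=C / U)
            if U == 1e-5:
                assert steady_u(syn, m) == pytest.approx(C * m / (1 + C * m), rel=1e-3)
        assert C * m / (1 + C * m) == pytest.approx(0.54669, abs=1e-4)


class TestDerivatives:
    def test_negative_state_rejected(self, reference):
        state = NetworkState.rested(reference)
        state.s[0] = -1e-3
        with pytest.raises(ValueError):
            derivatives(reference, state, {l: 0.0 for l in reference.labels})

    def test_pinned_variables_have_zero_derivative(self, reference):
        state = NetworkState.rested(reference)
        d = derivatives(reference, state, {"R": 0.05, "L": 0.02, "F": 0.01})
        for k, syn in enumerate(reference.synapses):
            if syn.tau_r == 0:
                assert d.x[k] == 0.0
            if syn.tau_f == 0:
                assert d.u[k] == 0.0
        assert np.all(d.a == 0.0)  # no adaptation in the base model


class TestReferenceCircuit:
    def test_eight_synapses_no_lts_lts(self, reference):
        assert len(reference.synapses) == 8
        assert reference.synapse("L", "L") is None

    def test_table_values(self, reference):
        assert reference.populations["R"].theta == 0.1
        assert reference.populations["R"].beta == 0.11
        assert reference.populations["L"].theta == 0.05
        assert reference.populations["L"].beta == 0.32
        assert reference.populations["F"].theta == 0.28
        assert reference.populations["F"].beta == 0.35
        lr = reference.synapse("L", "R")
        assert (lr.tau_s, lr.tau_f, lr.tau_r, lr.U, lr.g) == (2.0, 670.0, 0.0, 0.09, 7.0)
        rl = reference.synapse("R", "L")
        assert (rl.tau_s, rl.tau_r, rl.U, rl.g) == (6.3, 1250.0, 0.3, 35.0)

    def test_grr_disabled(self):
        spec = reference_circuit(g_rr=False)
        assert spec.synapse("R", "R").g == 0.0
        assert spec.synapse("F", "R").g == 18.0

    def test_signs_follow_presynaptic_type(self, reference):
        for syn in reference.synapses:
            assert syn.sign == (+1 if syn.pre == "R" else -1)

    def test_adaptation_matched_gain(self):
        spec = reference_circuit(adaptation=True)
        for lbl, pop in spec.populations.items():
            ad = pop.adaptation
            assert ad is not None
            assert ad.steady_gain == pytest.approx(pop.beta, rel=1e-12)


class TestReducedCircuit:
    def test_four_synapses_no_depression(self, reduced):
        assert len(reduced.synapses) == 4
        assert all(s.tau_r == 0.0 for s in reduced.synapses)
        assert {s.key for s in reduced.synapses} == {
            ("L", "R"), ("R", "L"), ("F", "R"), ("L", "F"),
        }

    def test_single_slow_variable(self, reduced):
        slow = [s for s in reduced.synapses if s.tau_f > 0]
        assert len(slow) == 1 and slow[0].key == ("L", "R")

    def test_caption_couplings(self, reduced):
        assert reduced.synapse("L", "R").g == 7.5
        assert reduced.synapse("F", "R").g == 9.3
        assert reduced.synapse("L", "F").g == 8.0
        assert reduced.synapse("R", "L").g == 35.0


def test_yaml_round_trip(tmp_path, reference):
    path = tmp_path / "circuit.yaml"
    spec = reference_circuit(adaptation=True)
    spec.to_yaml(path)
    loaded = CircuitSpec.from_yaml(path)
    assert loaded == spec


def test_duplicate_synapse_rejected():
    pops = {"R": PopulationParams(label="R", theta=0.1, beta=0.11)}
    syn = SynapseParams(pre="R", post="R", g=1.0, U=0.5, tau_s=2.0)
    with pytest.raises(ValueError):
        CircuitSpec(populations=pops, synapses=(syn, syn))
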