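"""Fixed points, thresholds, closed-form asymptotics, stability."""

import math

import numpy as np
import pytest

from stpnet import steady
from stpnet.circuit import reference_circuit, rs_fs_circuit, rs_lts_circuit
from stpnet.fixtures import randomized_circuit
from stpnet.metrics import measure_lts_delay
from stpnet.simulate import make_protocol, simulate


class TestSolveFixedPoint:
    def test_rs_only_linear_branch(self):
        spec = rs_lts_circuit(g_rl=0.0, g_lr=7.5)
        fps = steady.solve_fixed_point(spec, {"R": 0.5})
        stable = [f for f in fps if f.stable]
        assert len(stable) == 1
        assert stable[0].rates["R"] == pytest.approx(0.11 * 0.4, rel=1e-10)

    def test_residuals_are_zero(self, reference):
        """Every returned fixed point annihilates the vector field."""
        for inputs in ({"R": 0.2, "F": 0.28}, {"R": 0.44, "F": 0.33},
                       {"R": 0.05, "F": 0.1}):
            for fp in steady.solve_fixed_point(reference, inputs):
                assert steady.fixed_point_residual(reference, fp, inputs) < 1e-10

    def test_high_input_constant_reduction(self, rs_lts):
        """At large I_R the depressing LTS inhibition subtracts the constant
        beta_R g_RL tau_s,RL / tau_r,RL ~ 0.0194 ms^-1 from the RS rate."""
        i_r = 2.0
        fps = [f for f in steady.solve_fixed_point(rs_lts, {"R": i_r}) if f.stable]
        assert len(fps) == 1
        reduction = 0.11 * (i_r - 0.1) - fps[0].rates["R"]
        expected = 0.11 * 35.0 * 6.3 / 1250.0
        assert reduction == pytest.approx(expected, rel=0.01)
        # oracle: relaxation simulation
        traj = simulate(rs_lts, make_protocol("constant", R=i_r), t_end=30000.0,
                        record_stride=200)
        assert fps[0].rates["R"] == pytest.approx(traj.rate("R")[-1], abs=1e-6)

    def test_oracle_equivalence_on_random_neighbors(self, reference):
        """Stable fixed points match long-time simulation on randomized
        circuits near the reference (whenever the simulation rests)."""
        rng = np.random.default_rng(7)
        checked = 0
        for seed in range(40):
            spec = randomized_circuit(seed)
            inputs = {"R": float(rng.uniform(0.0, 0.5)),
                      "F": float(rng.uniform(0.0, 0.5))}
            traj = simulate(spec, make_protocol("constant", **inputs),
                            t_end=10000.0, record_stride=100)
            i_settle = np.searchsorted(traj.times, 8000.0)
            if np.max(np.abs(traj.rates[-1] - traj.rates[i_settle])) > 1e-7:
                continue  # still drifting; this draw has no usable oracle
            sim_rates = {l: float(traj.rate(l)[-1]) for l in spec.labels}
            fps = [f for f in steady.solve_fixed_point(spec, inputs) if f.stable]
            match = any(
                all(abs(f.rates[l] - sim_rates[l]) < 1e-6 for l in spec.labels)
                for f in fps
            )
            assert match, (seed, inputs, sim_rates, fps)
            checked += 1
        assert checked >= 15

    def test_monotone_in_inhibitory_couplings(self):
        """Steady M_R is non-increasing in g_RL and in g_RF."""
        rates = []
        for g_rl in (0.0, 17.5, 35.0):
            spec = rs_lts_circuit(g_rl=g_rl)
            fp = [f for f in steady.solve_fixed_point(spec, {"R": 0.4}) if f.stable][0]
            rates.append(fp.rates["R"])
        assert rates[0] >= rates[1] >= rates[2]
        rates = []
        for g_rf in (0.0, 25.0, 50.0):
            spec = rs_fs_circuit(g_rf=g_rf)
            fp = [f for f in steady.solve_fixed_point(spec, {"R": 0.4, "F": 0.35})
                  if f.stable][0]
            rates.append(fp.rates["R"])
        assert rates[0] >= rates[1] >= rates[2]

    def test_high_rate_gain_approaches_beta_r(self, reference):
        """d<M_R>/dI_R -> beta_R at large input for the full circuit."""
        def m_r(i_r):
            fps = [f for f in steady.solve_fixed_point(reference, {"R": i_r, "F": i_r})
                   if f.stable]
            return fps[0].rates["R"]

        slope = (m_r(4.1) - m_r(3.9)) / 0.2
        assert slope == pytest.approx(0.11, rel=0.02)


class TestStability:
    def test_all_silent_eigenvalues_are_relaxation_rates(self, reference):
        fps = steady.solve_fixed_point(reference, {"R": 0.0, "F": 0.0})
        assert len(fps) == 1 and fps[0].stable
        eig = np.sort(fps[0].eigenvalues.real)
        expected = sorted(
            [-1.0 / s.tau_s for s in reference.synapses]
            + [-1.0 / s.tau_r for s in reference.synapses if s.tau_r > 0]
            + [-1.0 / s.tau_f for s in reference.synapses if s.tau_f > 0]
        )
        np.testing.assert_allclose(eig, np.sort(expected), rtol=1e-9)

    def test_rest_regime_is_stable(self, reference):
        fps = [f for f in steady.solve_fixed_point(reference, {"R": 0.2, "F": 0.28})
               if f.stable]
        assert fps and fps[0].active == frozenset({"R", "F"})

    def test_stability_agrees_with_simulation_decay(self, rs_lts):
        """Perturbing a stable fixed point decays back in simulation."""
        fp = [f for f in steady.solve_fixed_point(rs_lts, {"R": 0.4}) if f.stable][0]
        state = fp.state.copy()
        state.s *= 1.05
        traj = simulate(rs_lts, make_protocol("constant", R=0.4), t_end=20000.0,
                        initial=state, record_stride=200)
        assert traj.rate("R")[-1] == pytest.approx(fp.rates["R"], abs=1e-8)


class TestLtsThreshold:
    def test_reference_value(self, rs_lts):
        th = steady.lts_threshold_input(rs_lts)
        assert th.input_threshold == pytest.approx(0.1765, abs=2e-4)
        # oracle: steady-state sweep detecting M_L > 0
        lo = th.input_threshold - 0.003
        hi = th.input_threshold + 0.003
        for i_r, expect in ((lo, False), (hi, True)):
            fps = [f for f in steady.solve_fixed_point(rs_lts, {"R": i_r}) if f.stable]
            assert ("L" in fps[0].active) == expect

    def test_threshold_decreases_with_g_lr(self):
        th1 = steady.lts_threshold_input(rs_lts_circuit(g_lr=7.5)).input_threshold
        th2 = steady.lts_threshold_input(rs_lts_circuit(g_lr=15.0)).input_threshold
        assert th2 < th1

    def test_large_g_lr_limit_is_theta_r(self):
        th = steady.lts_threshold_input(rs_lts_circuit(g_lr=1e7)).input_threshold
        assert th == pytest.approx(0.1, abs=1e-3)

    def test_tonic_lts_input_lowers_threshold(self, rs_lts):
        t0 = steady.lts_threshold_input(rs_lts, I_L=0.0).input_threshold
        t1 = steady.lts_threshold_input(rs_lts, I_L=0.04).input_threshold
        assert t1 < t0


class TestRsGainAtThreshold:
    def test_no_inhibition_gives_beta_r(self):
        assert steady.rs_gain_at_lts_threshold(rs_lts_circuit(g_rl=0.0)) == 0.11

    def test_scales_inversely_with_g_rl(self):
        g1 = steady.rs_gain_at_lts_threshold(rs_lts_circuit(g_rl=17.5))
        g2 = steady.rs_gain_at_lts_threshold(rs_lts_circuit(g_rl=35.0))
        assert g2 < g1
        assert g1 / g2 == pytest.approx(2.0, rel=0.1)

    def test_independent_of_depression_recovery(self):
        vals = [
            steady.rs_gain_at_lts_threshold(
                rs_lts_circuit().with_synapse("R", "L", tau_r=tr)
            )
            for tr in (0.0, 150.0, 1250.0)
        ]
        assert max(vals) - min(vals) < 1e-12

    def test_matches_numeric_slope_above_threshold(self, rs_lts):
        th = steady.lts_threshold_input(rs_lts)
        gain = steady.rs_gain_at_lts_threshold(rs_lts)
        eps = 2e-4
        def m_r(i_r):
            return [f for f in steady.solve_fixed_point(rs_lts, {"R": i_r})
                    if f.stable][0].rates["R"]
        numeric = (m_r(th.input_threshold + 2 * eps) - m_r(th.input_threshold + eps)) / eps
        assert numeric == pytest.approx(gain, rel=0.02)


class TestFsMaxRate:
    def test_explicit_when_no_self_inhibition(self):
        spec = rs_fs_circuit(g_ff=0.0)
        fr = spec.synapse("F", "R")
        expected = 0.35 * (0.35 + fr.g * fr.tau_s / fr.tau_r - 0.28)
        assert steady.fs_max_rate(spec, I_F=0.35) == pytest.approx(expected, rel=1e-12)

    def test_self_inhibition_reduces_maximum(self):
        m0 = steady.fs_max_rate(rs_fs_circuit(g_ff=0.0), I_F=0.35)
        m5 = steady.fs_max_rate(rs_fs_circuit(g_ff=5.0), I_F=0.35)
        m10 = steady.fs_max_rate(rs_fs_circuit(g_ff=10.0), I_F=0.35)
        assert m0 > m5 > m10

    def test_matches_simulated_saturation(self, rs_fs):
        """Simulated M_F approaches the implicit-equation limit from below."""
        m_max = steady.fs_max_rate(rs_fs, I_F=0.35)
        sims = []
        for i_r in (3.0, 10.0, 30.0):
            traj = simulate(rs_fs, make_protocol("constant", R=i_r, F=0.35),
                            t_end=20000.0, record_stride=200)
            sims.append(traj.rate("F")[-1])
        assert sims[0] < sims[1] < sims[2] < m_max
        assert sims[0] == pytest.approx(m_max, rel=0.05)
        assert sims[2] == pytest.approx(m_max, rel=0.01)
        # frozen regression value for this RS-FS configuration
        assert m_max == pytest.approx(0.09356, abs=1e-4)


class TestDelayClosedForm:
    def test_below_threshold_is_infinite(self, rs_lts):
        assert math.isinf(steady.delay_time_closed_form(rs_lts, I_R=0.15))

    def test_monotone_decreasing_in_input(self, rs_lts):
        grid = np.linspace(0.2, 0.5, 10)
        vals = [steady.delay_time_closed_form(rs_lts, i) for i in grid]
        finite = [v for v in vals if math.isfinite(v)]
        assert all(a > b for a, b in zip(finite, finite[1:]))

    def test_diverges_near_threshold_and_small_far_above(self, rs_lts):
        th = steady.lts_threshold_input(rs_lts).input_threshold
        near = steady.delay_time_closed_form(rs_lts, th + 1e-4)
        far = steady.delay_time_closed_form(rs_lts, 2.0)
        assert near > 2000.0
        assert far < 5 * rs_lts.synapse("L", "R").tau_s

    @pytest.mark.parametrize("i_r", [0.25, 0.3, 0.38, 0.44, 0.5])
    def test_matches_simulated_onset_within_2pct(self, rs_lts, i_r):
        closed = steady.delay_time_closed_form(rs_lts, i_r)
        traj = simulate(rs_lts, make_protocol("step", R=i_r),
                        t_end=closed * 3 + 200.0)
        measured = measure_lts_delay(traj)
        assert measured == pytest.approx(closed, rel=0.02)


class TestRrBistability:
    def test_no_recurrence_no_bistability(self):
        spec = rs_lts_circuit(g_rr=0.0)
        res = steady.detect_rr_bistability(
            rs_lts_circuit(g_rr=1e-9), np.linspace(0.05, 0.3, 8)
        )
        assert res.bistable_inputs == [] and res.M_R_c is None
        # M_R continuous in I_R
        fps = [
            [f for f in steady.solve_fixed_point(spec, {"R": i}) if f.stable][0].rates["R"]
            for i in np.linspace(0.05, 0.3, 8)
        ]
        assert np.all(np.diff(fps) >= 0) and np.all(np.diff(fps) < 0.02)

    def test_strong_recurrence_creates_forbidden_band(self):
        spec = rs_lts_circuit(g_rr=40.0)
        res = steady.detect_rr_bistability(spec, np.linspace(0.02, 0.12, 11))
        assert res.bistable_inputs, "expected rest/active coexistence"
        assert res.M_R_c is not None and res.M_R_c > 1e-4

    def test_slower_rr_recovery_weakens_boost(self):
        """Larger tau_r,RR means deeper depression of the recurrent boost."""
        rates = []
        for tau_r in (60.0, 463.0, 1000.0):
            spec = rs_lts_circuit(g_rr=40.0).with_synapse("R", "R", tau_r=tau_r)
            fps = [f for f in steady.solve_fixed_point(spec, {"R": 0.4}) if f.stable]
            rates.append(max(f.rates["R"] for f in fps))
        assert rates[0] > rates[1] > rates[2]
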