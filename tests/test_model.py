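"""Unit tests for the CA1 conductance-based model and its integrators."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ephysgan import model as M

from conftest import leak_only_params


# ---------------------------------------------------------------------------
# Gating primitives
# ---------------------------------------------------------------------------

class TestBoltzmann:
    def test_half_activation_at_v_half(self):
        for k in (2.0, -7.5, 10.0):
            assert M.boltzmann(-30.0, -30.0, k) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert M.boltzmann(200.0, -30.0, 5.0) == pytest.approx(1.0, abs=1e-9)
        assert M.boltzmann(-300.0, -30.0, 5.0) == pytest.approx(0.0, abs=1e-9)

    def test_one_slope_above_half(self):
        # V = V_x + k_x gives 1/(1 + e^-1)
        assert M.boltzmann(-25.0, -30.0, 5.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-1.0)), abs=1e-12)

    @given(V=st.floats(-120, 60), vh=st.floats(-90, 0),
           k=st.floats(1.0, 15.0))
    def test_strictly_inside_unit_interval(self, V, vh, k):
        x = M.boltzmann(V, vh, k)
        assert 0.0 < x <= 1.0
        if (V - vh) / k < 30:  # away from float saturation of the sigmoid
            assert x < 1.0

    def test_rejects_zero_slope_and_nonfinite_v(self):
        with pytest.raises(ValueError):
            M.boltzmann(-50.0, -30.0, 0.0)
        with pytest.raises(ValueError):
            M.boltzmann(np.nan, -30.0, 5.0)


class TestTauHNaT:
    def test_value_at_inner_exponent_zero(self):
        # V = 40.6 makes the inner exponent zero: tau = 0.2 + 0.007*e
        assert M.tau_h_nat(40.6) == pytest.approx(0.2 + 0.007 * np.e, abs=1e-12)

    def test_large_v_limit(self):
        assert M.tau_h_nat(1e4) == pytest.approx(0.207, abs=1e-4)

    def test_monotone_decreasing(self):
        V = np.linspace(-120.0, 60.0, 500)
        tau = M.tau_h_nat(V)
        assert np.all(np.diff(tau) < 0)
        assert np.all(tau > 0.2)


# ---------------------------------------------------------------------------
# Right-hand side against an independently coded sum of currents
# ---------------------------------------------------------------------------

def _oracle_ionic_current(V, gates, p):
    """Independent re-implementation of the eight-current table."""
    gs = {g.name: g for g in p.gating}
    x = dict(zip([M.GATE_NAMES[i] for i in M.DYNAMIC_GATES], gates))
    b = lambda name: 1.0 / (1.0 + np.exp(-(V - gs[name].v_half) / gs[name].k))
    return sum([
        p.g_NaT * b("m_NaT") ** 3 * x["h_NaT"] * (V - p.E_Na),
        p.g_NaP * b("m_NaP") * (V - p.E_Na),
        p.g_CaT * x["m_CaT"] ** 2 * x["h_CaT"] * (V - p.E_Ca),
        p.g_CaH * x["m_CaH"] ** 2 * x["h_CaH"] * (V - p.E_Ca),
        p.g_KDR * x["m_KDR"] * x["h_KDR"] * (V - p.E_K),
        p.g_KM * x["m_KM"] * (V - p.E_K),
        p.g_L * (V - p.E_L),
        p.g_H * (p.p * x["m_H"] + (1 - p.p) * x["n_H"]) * (V - p.E_H),
    ])


class TestRHS:
    def test_leak_only_fixed_point(self, leak_params):
        proto = M.StimulusProtocol(bias_current=0.0, pulse_amplitude=0.0,
                                   pulse_onset=0.0, pulse_duration=0.0,
                                   total_duration=10.0)
        state = np.concatenate(([leak_params.E_L],
                                leak_params.gates_inf(leak_params.E_L)))
        dy = M.rhs(0.0, state, leak_params, proto, 0.0)
        assert dy[0] == pytest.approx(0.0, abs=1e-12)

    def test_gate_equilibrium_has_zero_gate_derivatives(self, default_params):
        proto = M.depolarizing_protocol(bias_current=0.0)
        V = -55.0
        state = np.concatenate(([V], default_params.gates_inf(V)))
        dy = M.rhs(0.0, state, default_params, proto, 0.0)
        assert np.allclose(dy[1:], 0.0, atol=1e-12)

    def test_matches_independent_current_sum(self, default_params):
        rng = np.random.default_rng(0)
        proto = M.depolarizing_protocol(bias_current=0.3)
        for _ in range(20):
            V = rng.uniform(-100, 40)
            gates = rng.uniform(0, 1, 10)
            state = np.concatenate(([V], gates))
            t = rng.uniform(0, proto.total_duration)
            dV = M.rhs(t, state, default_params, proto, 0.3)[0]
            I_app = proto.applied_current(t, 0.3)
            expected = (I_app - _oracle_ionic_current(V, gates, default_params)
                        ) / default_params.C
            assert dV == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_leak_only_rc_decay_closed_form(self, leak_params):
        V0 = -50.0
        proto = M.StimulusProtocol(
            hold_target=V0, bias_current=0.0, pulse_amplitude=0.0,
            pulse_onset=0.0, pulse_duration=0.0, total_duration=100.0,
            settle_duration=0.0)
        init = np.concatenate(([V0], leak_params.gates_inf(V0)))
        tr = M.simulate(leak_params, proto, init=init)
        expected = leak_params.E_L + (V0 - leak_params.E_L) * np.exp(
            -leak_params.g_L * tr.t / leak_params.C)
        rel = np.abs(tr.V - expected) / np.abs(V0 - leak_params.E_L)
        assert rel.max() < 1e-6

    def test_default_cell_fires_under_depolarizing_protocol(
            self, default_traces):
        dep, _ = default_traces
        m = (dep.t >= dep.protocol.pulse_onset) & \
            (dep.t <= dep.protocol.pulse_onset + dep.protocol.pulse_duration)
        assert dep.V[m].max() > 0.0

    def test_quiescent_after_settling_without_pulse(self, default_params):
        proto = M.StimulusProtocol(pulse_amplitude=0.0, pulse_onset=0.0,
                                   pulse_duration=0.0, total_duration=500.0,
                                   dt_out=0.5, settle_duration=200.0)
        tr = M.simulate(default_params, proto)
        assert tr.V.max() - tr.V.min() < 0.01

    def test_conductance_capacitance_current_scaling_invariance(
            self, default_params, dep_protocol):
        """Doubling C, every g, and I_app jointly leaves V(t) unchanged."""
        bias = M.find_bias_current(default_params, verify=False)
        scaled = default_params.replace(
            C=2 * default_params.C,
            **{n: 2 * getattr(default_params, n) for n in M.CONDUCTANCE_NAMES})
        p1 = M.StimulusProtocol(bias_current=bias, dt_out=0.02)
        p2 = M.StimulusProtocol(
            bias_current=2 * bias,
            pulse_amplitude=2 * p1.pulse_amplitude, dt_out=0.02)
        t1, V1, s1 = M.simulate_batch([default_params], p1)
        t2, V2, s2 = M.simulate_batch([scaled], p2)
        assert s1[0] == 0 and s2[0] == 0
        assert np.abs(V1 - V2).max() < 1e-9

    def test_gates_stay_in_unit_interval_across_parameter_box(
            self, default_params, dep_protocol):
        rng = np.random.default_rng(42)
        mult = rng.uniform(0, 2, (20, 5))
        sets = [default_params.replace(
            g_NaT=35 * m[0], g_CaH=1.6 * m[1], g_KDR=6 * m[2],
            g_KM=1.0 * m[3], g_H=0.10 * m[4]) for m in mult]
        _, _, status = M.simulate_batch(sets, dep_protocol)
        assert not np.any(status == 2)   # 2 = gate outside [0,1] + 1e-9


class TestFindBiasCurrent:
    def test_leak_only_at_leak_reversal_is_zero(self, leak_params):
        assert M.find_bias_current(leak_params, leak_params.E_L) == \
            pytest.approx(0.0, abs=1e-12)

    def test_leak_only_ohmic_offset(self, leak_params):
        target = leak_params.E_L + 10.0
        assert M.find_bias_current(leak_params, target) == pytest.approx(
            leak_params.g_L * 10.0, abs=1e-12)

    def test_default_cell_settles_at_hold_target(self, default_params):
        bias = M.find_bias_current(default_params, -80.0, verify=False)
        proto = M.StimulusProtocol(
            bias_current=bias, pulse_amplitude=0.0, pulse_onset=0.0,
            pulse_duration=0.0, total_duration=1000.0, dt_out=1.0,
            settle_duration=0.0)
        tr = M.simulate(default_params, proto)
        assert abs(tr.V[-1] + 80.0) < 0.1

    def test_rejects_hold_outside_reversal_range(self, default_params):
        with pytest.raises(ValueError):
            M.find_bias_current(default_params, default_params.E_Na + 10)


class TestBatchKernel:
    def test_matches_adaptive_solver_on_default_cell(
            self, default_params, dep_protocol, default_traces):
        dep, _ = default_traces
        ref = M.simulate(default_params, dep_protocol)
        assert np.abs(dep.V - ref.V).max() < 0.5

    def test_rejects_incompatible_output_grid(self, default_params):
        with pytest.raises(ValueError):
            M.simulate_batch([default_params], M.depolarizing_protocol(),
                             dt=0.03)


class TestValidation:
    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            M.default_parameters().replace(g_NaT=-1.0)

    def test_bad_fast_fraction_rejected(self):
        with pytest.raises(ValueError):
            M.default_parameters().replace(p=1.5)

    def test_pulse_must_fit_in_window(self):
        with pytest.raises(ValueError):
            M.StimulusProtocol(pulse_onset=400.0, pulse_duration=500.0,
                               total_duration=700.0)

    def test_gating_spec_invariants(self):
        with pytest.raises(ValueError):
            M.GatingSpec("m_X", -30.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            M.GatingSpec("m_X", -30.0, 5.0, -1.0)
        with pytest.raises(ValueError):
            M.GatingSpec("m_X", -30.0, 5.0, 1.0, power=4)
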