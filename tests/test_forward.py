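"""Forward simulator: closed-form integration, threshold crossings,
spike transitions, and agreement with dense numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from eventprop import (
    InputSpikeTrain,
    NetworkConfig,
    NeuronState,
    apply_input_spike,
    apply_spike_transition,
    evolve_free,
    next_threshold_crossing,
    simulate,
)
from eventprop.forward import CriticalPointWarning, free_solution

from conftest import make_random_net


def single_neuron_config(w=0.0, tau_mem=20.0, tau_syn=5.0, t_end=100.0):
    return NetworkConfig(tau_mem=tau_mem, tau_syn=tau_syn,
                         w_rec=np.zeros((1, 1)), w_in=np.array([[w]]),
                         t_end=t_end)


def ode_oracle(v0, i0, dt, tau_mem, tau_syn):
    """Adaptive-step integration of the free dynamics."""
    n = len(v0)

    def rhs(t, x):
        v, i = x[:n], x[n:]
        return np.concatenate([(-v + i) / tau_mem, -i / tau_syn])

    sol = solve_ivp(rhs, (0, dt), np.concatenate([v0, i0]),
                    rtol=1e-12, atol=1e-14, dense_output=True)
    x = sol.y[:, -1]
    return x[:n], x[n:]


class TestEvolveFree:
    def test_pure_leak(self):
        cfg = single_neuron_config()
        s = NeuronState(0.0, np.array([1.0]), np.array([0.0]))
        out = evolve_free(s, cfg.tau_mem, cfg)
        assert out.v[0] == pytest.approx(np.exp(-1.0), rel=1e-14)
        assert out.i[0] == 0.0

    def test_dt_zero_identity(self):
        cfg = single_neuron_config()
        s = NeuronState(3.0, np.array([0.4]), np.array([1.2]))
        out = evolve_free(s, 0.0, cfg)
        assert out.v[0] == s.v[0] and out.i[0] == s.i[0] and out.t == s.t

    def test_against_ode_oracle(self):
        cfg = single_neuron_config()
        s = NeuronState(0.0, np.array([0.0]), np.array([2.0]))
        out = evolve_free(s, 3.0, cfg)
        v_ref, i_ref = ode_oracle(s.v, s.i, 3.0, 20.0, 5.0)
        assert abs(out.v[0] - v_ref[0]) <= 1e-10
        assert abs(out.i[0] - i_ref[0]) <= 1e-10

    def test_rejects_equal_time_constants(self):
        with pytest.raises(ValueError, match="alpha"):
            NetworkConfig(tau_mem=5.0, tau_syn=5.0,
                          w_rec=np.zeros((1, 1)), w_in=np.zeros((1, 1)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(v0=st.floats(-2, 2), i0=st.floats(-3, 3),
           dt=st.floats(0, 50),
           tau_mem=st.floats(5, 40), tau_syn=st.floats(0.5, 4.5))
    def test_closed_form_matches_ode(self, v0, i0, dt, tau_mem, tau_syn):
        v, i = free_solution(np.array([v0]), np.array([i0]), dt,
                             tau_mem, tau_syn)
        v_ref, i_ref = ode_oracle(np.array([v0]), np.array([i0]), dt,
                                  tau_mem, tau_syn)
        scale = max(abs(v_ref[0]), abs(i_ref[0]), 1e-6)
        assert abs(v[0] - v_ref[0]) / scale <= 1e-9
        assert abs(i[0] - i_ref[0]) / scale <= 1e-9


class TestThresholdCrossing:
    def test_decaying_potential_never_crosses(self):
        cfg = single_neuron_config()
        s = NeuronState(0.0, np.array([0.5]), np.array([0.0]))
        assert next_threshold_crossing(s, 100.0, cfg) is None

    def test_matches_dense_scan(self):
        cfg = single_neuron_config()
        s = NeuronState(0.0, np.array([0.0]), np.array([8.0]))
        t_star, n = next_threshold_crossing(s, 100.0, cfg)
        assert n == 0
        ts = np.arange(0.0, 30.0, 1e-5)
        v, _ = free_solution(s.v[0], s.i[0], ts, 20.0, 5.0)
        t_dense = ts[np.argmax(v >= 1.0)]
        assert abs(t_star - t_dense) <= 1e-5 + 1e-6

    def test_larger_current_crosses_first(self):
        cfg = NetworkConfig(20.0, 5.0, np.zeros((2, 2)), np.zeros((2, 1)),
                            t_end=100.0)
        s = NeuronState(0.0, np.zeros(2), np.array([4.0, 8.0]))
        t_star, n = next_threshold_crossing(s, 100.0, cfg)
        assert n == 1
        # dense-scan check for the winning neuron
        ts = np.arange(0.0, 20.0, 1e-5)
        v, _ = free_solution(0.0, 8.0, ts, 20.0, 5.0)
        assert abs(t_star - ts[np.argmax(v >= 1.0)]) <= 2e-5


class TestSpikeTransition:
    def test_jump_rule(self):
        w = 0.7
        cfg = NetworkConfig(20.0, 5.0, np.array([[0.0, 0.0], [w, 0.0]]),
                            np.zeros((2, 1)))
        s = NeuronState(0.0, np.array([1.0, 0.3]), np.array([2.0, 0.1]))
        out = apply_spike_transition(s, 0, cfg)
        assert out.v[0] == 0.0
        assert out.v[1] == 0.3
        assert out.i[1] == pytest.approx(0.1 + w)
        assert out.i[0] == 2.0  # zero diagonal: no self-jump

    def test_zero_weights_only_reset(self):
        cfg = NetworkConfig(20.0, 5.0, np.zeros((2, 2)), np.zeros((2, 1)))
        s = NeuronState(0.0, np.array([1.0, 0.2]), np.array([1.5, 0.0]))
        out = apply_spike_transition(s, 0, cfg)
        assert out.v[0] == 0.0
        assert np.array_equal(out.i, s.i)

    def test_coincident_transitions_commute(self):
        w = np.array([[0.0, 0.3], [0.5, 0.0]])
        cfg = NetworkConfig(20.0, 5.0, w, np.zeros((2, 1)))
        s = NeuronState(0.0, np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        ab = apply_spike_transition(apply_spike_transition(s, 0, cfg), 1, cfg)
        ba = apply_spike_transition(apply_spike_transition(s, 1, cfg), 0, cfg)
        assert np.array_equal(ab.i, ba.i)
        assert np.array_equal(ab.v, ba.v)

    def test_warns_near_critical_slope(self):
        cfg = single_neuron_config()
        s = NeuronState(0.0, np.array([1.0]), np.array([1.0 + 1e-12]))
        with pytest.warns(CriticalPointWarning):
            apply_spike_transition(s, 0, cfg)


class TestInputSpike:
    def test_zero_column_noop(self):
        cfg = single_neuron_config(w=0.0)
        s = NeuronState(0.0, np.array([0.3]), np.array([0.2]))
        out = apply_input_spike(s, 0, cfg)
        assert out.i[0] == s.i[0] and out.v[0] == s.v[0]

    def test_initial_condition_setup(self):
        # one input spike at t=0 into a fresh neuron: I(0+)=w, V(0)=0
        w = 1.3
        cfg = single_neuron_config(w=w)
        s = NeuronState.zero(1)
        out = apply_input_spike(s, 0, cfg)
        assert out.i[0] == w and out.v[0] == 0.0

    def test_simultaneous_spikes_add(self):
        w = 0.4
        cfg = single_neuron_config(w=w)
        s = NeuronState.zero(1)
        out = apply_input_spike(apply_input_spike(s, 0, cfg), 0, cfg)
        assert out.i[0] == pytest.approx(2 * w)


class TestSimulate:
    def test_zero_weights_empty_record(self):
        cfg = NetworkConfig(20.0, 5.0, np.zeros((3, 3)), np.zeros((3, 2)))
        inputs = InputSpikeTrain(np.array([1.0, 2.0]), np.array([0, 1]))
        record, _ = simulate(cfg, inputs)
        assert len(record) == 0

    def test_spikes_occur_at_threshold_with_cached_slope(self):
        cfg = single_neuron_config(w=3.0, t_end=60.0)
        inputs = InputSpikeTrain(np.array([0.0, 2.0, 4.0]),
                                 np.array([0, 0, 0]))
        record, traj = simulate(cfg, inputs)
        assert len(record) >= 1
        for ev in record:
            v, i = traj.state_at(ev.time - 1e-9)
            assert abs(v[ev.neuron] - 1.0) <= 1e-6
            assert ev.vdot_minus == pytest.approx(
                (-1.0 + ev.i_minus) / cfg.tau_mem)
            assert ev.vdot_minus != 0.0

    def test_determinism(self):
        cfg, inputs = make_random_net(3)
        r1, _ = simulate(cfg, inputs)
        r2, _ = simulate(cfg, inputs)
        assert [(e.time, e.neuron, e.i_minus, e.vdot_minus) for e in r1] \
            == [(e.time, e.neuron, e.i_minus, e.vdot_minus) for e in r2]

    @pytest.mark.parametrize("delta", [2.5, 7.0])
    def test_time_translation_invariance(self, delta):
        cfg, inputs = make_random_net(5)
        rec, _ = simulate(cfg, inputs)
        assert len(rec) > 0
        cfg2 = NetworkConfig(cfg.tau_mem, cfg.tau_syn, cfg.w_rec, cfg.w_in,
                             firing_mask=cfg.firing_mask,
                             t_end=cfg.t_end + delta)
        inputs2 = InputSpikeTrain(inputs.times + delta, inputs.channels)
        rec2, _ = simulate(cfg2, inputs2)
        assert len(rec) == len(rec2)
        np.testing.assert_allclose(rec2.times, rec.times + delta,
                                   atol=1e-9)
        assert np.array_equal(rec.neurons, rec2.neurons)

    def test_runaway_guard(self):
        # strong self-excitation through a 2-cycle explodes
        w = np.array([[0.0, 5.0], [5.0, 0.0]])
        cfg = NetworkConfig(20.0, 5.0, w, np.full((2, 1), 8.0),
                            t_end=200.0, spike_cap=500)
        inputs = InputSpikeTrain(np.array([0.0]), np.array([0]))
        with pytest.raises(RuntimeError, match="runaway"):
            simulate(cfg, inputs)

    def test_trajectory_tiles_horizon(self):
        cfg, inputs = make_random_net(11)
        _, traj = simulate(cfg, inputs)
        assert traj.segments[0].t_start == 0.0
        assert traj.segments[-1].t_end == cfg.t_end
        for a, b in zip(traj.segments[:-1], traj.segments[1:]):
            assert a.t_end == b.t_start
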