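"""Loss heads: first-spike bookkeeping, softmax cross-entropies, voltage
maxima, and their analytic sensitivities."""

import numpy as np
import pytest

from eventprop import (
    FiniteDiffSpec,
    InputSpikeTrain,
    MaxVoltageLossConfig,
    MaxVoltageLossHead,
    NetworkConfig,
    SpikeRecord,
    TTFSLossConfig,
    central_difference_gradient,
    eventprop_gradient,
    first_spike_times,
    max_voltage_loss,
    simulate,
    ttfs_loss,
    voltage_max,
)
from eventprop.losses import FirstSpikeTable, MISSING
from eventprop.network import SpikeEvent


def record_from(pairs):
    rec = SpikeRecord()
    for t, n in pairs:
        rec.events.append(SpikeEvent(t, n, 1.5, 0.025))
    return rec


CFG3 = TTFSLossConfig(output_neurons=(0, 1, 2))


class TestFirstSpikes:
    def test_earliest_wins(self):
        rec = record_from([(5.0, 0), (9.0, 0)])
        table = first_spike_times(rec, CFG3)
        assert table.times[0] == 5.0
        assert table.event_indices[0] == 0

    def test_silent_neuron_missing(self):
        table = first_spike_times(record_from([(5.0, 0)]), CFG3)
        assert table.times[1] == MISSING
        assert table.event_indices[1] == -1

    def test_interleaved_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        pairs = [(float(rng.uniform(0, 40)), int(rng.integers(0, 3)))
                 for _ in range(30)]
        pairs.sort()
        table = first_spike_times(record_from(pairs), CFG3)
        for k in range(3):
            mine = [t for t, n in pairs if n == k]
            assert table.times[k] == (min(mine) if mine else MISSING)


class TestTTFSLoss:
    def test_uniform_softmax_is_log3(self):
        cfg = TTFSLossConfig(output_neurons=(0, 1, 2), alpha=0.0)
        table = FirstSpikeTable(np.array([7.0, 7.0, 7.0]),
                                np.array([0, 1, 2]))
        loss, _ = ttfs_loss(table, 1, cfg)
        assert loss == pytest.approx(np.log(3.0), rel=1e-12)

    def test_regulariser_vanishes_at_zero_time(self):
        cfg = TTFSLossConfig(output_neurons=(0, 1, 2), alpha=0.5)
        table = FirstSpikeTable(np.array([0.0, 0.0, 0.0]),
                                np.array([0, 1, 2]))
        loss, _ = ttfs_loss(table, 0, cfg)
        assert loss == pytest.approx(np.log(3.0), rel=1e-12)

    def test_sensitivities_match_finite_differences(self):
        cfg = CFG3
        rng = np.random.default_rng(3)
        times = rng.uniform(5, 15, 3)
        table = FirstSpikeTable(times.copy(), np.arange(3))
        _, sens = ttfs_loss(table, 2, cfg)
        eps = 1e-6
        for k in range(3):
            up = times.copy(); up[k] += eps
            dn = times.copy(); dn[k] -= eps
            lu, _ = ttfs_loss(FirstSpikeTable(up, np.arange(3)), 2, cfg)
            ld, _ = ttfs_loss(FirstSpikeTable(dn, np.arange(3)), 2, cfg)
            fd = (lu - ld) / (2 * eps)
            assert sens.dlp_dtpost[k] == pytest.approx(fd, rel=1e-8)

    def test_shift_moves_only_regulariser(self):
        cfg = CFG3
        times = np.array([4.0, 9.0, 6.0])
        l0, _ = ttfs_loss(FirstSpikeTable(times, np.arange(3)), 1, cfg)
        l1, _ = ttfs_loss(FirstSpikeTable(times + 3.0, np.arange(3)), 1, cfg)
        reg0 = cfg.alpha * (np.exp(times[1] / cfg.tau1) - 1)
        reg1 = cfg.alpha * (np.exp((times[1] + 3.0) / cfg.tau1) - 1)
        assert l1 - l0 == pytest.approx(reg1 - reg0, rel=1e-9)

    def test_class_permutation_equivariance(self):
        cfg = CFG3
        times = np.array([4.0, 9.0, 6.0])
        perm = [2, 0, 1]  # new position p holds old class perm[p]
        _, sens = ttfs_loss(FirstSpikeTable(times, np.arange(3)), 1, cfg)
        _, sens_p = ttfs_loss(
            FirstSpikeTable(times[perm], np.arange(3)), perm.index(1), cfg)
        for new_pos, old in enumerate(perm):
            assert sens_p.dlp_dtpost[new_pos] == pytest.approx(
                sens.dlp_dtpost[old], rel=1e-12)

    def test_silent_label_penalty_and_zero_gradient(self):
        cfg = TTFSLossConfig(output_neurons=(0, 1, 2), missing_penalty=42.0)
        table = FirstSpikeTable(np.array([4.0, MISSING, 6.0]),
                                np.array([0, -1, 2]))
        loss, sens = ttfs_loss(table, 1, cfg)
        assert loss == 42.0
        assert sens.dlp_dtpost == {}


class TestVoltageMax:
    def one_neuron_traj(self, w, t_spike=0.0, t_end=50.0):
        cfg = NetworkConfig(20.0, 5.0, np.zeros((1, 1)), np.array([[w]]),
                            firing_mask=np.array([False]), t_end=t_end)
        inputs = InputSpikeTrain(np.array([t_spike]), np.array([0]))
        _, traj = simulate(cfg, inputs)
        return traj

    def test_matches_dense_scan(self):
        traj = self.one_neuron_traj(1.7)
        t_star, v_max = voltage_max(traj, 0)
        ts = np.arange(0.0, 50.0, 1e-4)
        vs = traj.sample(ts[::100], 0)  # coarse pre-check
        dense_t = ts[::100][np.argmax(vs)]
        fine = np.arange(max(0, dense_t - 0.5), dense_t + 0.5, 1e-4)
        vf = traj.sample(fine, 0)
        assert v_max >= vf.max() - 1e-8
        assert abs(t_star - fine[np.argmax(vf)]) <= 1e-3

    def test_zero_drive(self):
        traj = self.one_neuron_traj(0.0)
        t_star, v_max = voltage_max(traj, 0)
        assert v_max == 0.0 and t_star == 0.0

    def test_late_spike_boundary_maximum(self):
        # input arrives so late that V is still rising at T: the maximum
        # sits on the final segment endpoint
        traj = self.one_neuron_traj(1.7, t_spike=48.0, t_end=50.0)
        t_star, v_max = voltage_max(traj, 0)
        assert t_star == pytest.approx(50.0)
        v_end, _ = traj.state_at(50.0)
        assert v_max == pytest.approx(v_end[0])


class TestMaxVoltageLoss:
    def test_uniform_softmax_is_log10(self):
        cfg = MaxVoltageLossConfig(readout_neurons=tuple(range(10)))
        vmax = np.full(10, 0.37)
        loss, _ = max_voltage_loss(vmax, np.zeros(10), 4, cfg)
        assert loss == pytest.approx(np.log(10.0), rel=1e-12)

    def test_jump_magnitudes_sum_to_zero(self):
        cfg = MaxVoltageLossConfig(readout_neurons=tuple(range(10)))
        rng = np.random.default_rng(8)
        vmax = rng.uniform(0, 2, 10)
        _, sens = max_voltage_loss(vmax, np.zeros(10), 3, cfg)
        total = sum(m for _, _, m in sens.voltage_jumps)
        assert total == pytest.approx(0.0, abs=1e-14)

    def test_class_permutation_equivariance(self):
        cfg = MaxVoltageLossConfig(readout_neurons=(0, 1, 2))
        vmax = np.array([0.4, 1.1, 0.2])
        ts = np.array([3.0, 7.0, 5.0])
        perm = [1, 2, 0]
        _, s = max_voltage_loss(vmax, ts, 0, cfg)
        _, sp = max_voltage_loss(vmax[perm], ts[perm], perm.index(0), cfg)
        mags = {n: m for _, n, m in s.voltage_jumps}
        for new_pos, old in enumerate(perm):
            assert sp.voltage_jumps[new_pos][2] == pytest.approx(
                mags[old], rel=1e-12)

    def test_end_to_end_gradient_vs_central_differences(self):
        # 2 hidden LIF + 3 non-firing readouts
        rng = np.random.default_rng(12)
        n_h, n_o = 2, 3
        n = n_h + n_o
        w_in = np.zeros((n, 2))
        w_in[:n_h] = rng.normal(2.2, 0.4, (n_h, 2))
        w_rec = np.zeros((n, n))
        w_rec[n_h:, :n_h] = rng.normal(0.8, 0.3, (n_o, n_h))
        mask = np.ones(n, bool)
        mask[n_h:] = False
        cfg = NetworkConfig(20.0, 5.0, w_rec, w_in, firing_mask=mask,
                            t_end=40.0)
        inputs = InputSpikeTrain(np.array([0.0, 5.0, 9.0]),
                                 np.array([0, 1, 0]))
        head = MaxVoltageLossHead(
            MaxVoltageLossConfig(tuple(range(n_h, n))), label=1)
        _, g = eventprop_gradient(cfg, inputs, head)
        entries = [("rec", j, i) for j in range(n_h, n) for i in range(n_h)]
        entries += [("in", j, c) for j in range(n_h) for c in range(2)]
        fd, crit = central_difference_gradient(
            cfg, inputs, head, entries, FiniteDiffSpec(epsilon=1e-6))
        ep = np.array([g.g_rec[j, i] if k == "rec" else g.g_in[j, i]
                       for k, j, i in entries])
        ok = ~crit & (np.abs(fd) > 1e-12)
        assert ok.sum() >= 4
        rel = np.abs(ep[ok] - fd[ok]) / np.abs(fd[ok])
        assert rel.max() <= 1e-6

    def test_rejects_firing_readouts(self):
        cfg = NetworkConfig(20.0, 5.0, np.zeros((2, 2)), np.zeros((2, 1)),
                            t_end=10.0)
        inputs = InputSpikeTrain(np.array([0.0]), np.array([0]))
        head = MaxVoltageLossHead(MaxVoltageLossConfig((0, 1)), label=0)
        record, traj = simulate(cfg, inputs)
        with pytest.raises(ValueError, match="non-firing"):
            head.evaluate(record, traj, cfg)
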