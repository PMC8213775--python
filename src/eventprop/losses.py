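"""Loss heads: first-spike-time cross-entropy and max-over-time voltage
cross-entropy.

Each head evaluates a scalar loss on the forward pass output and produces
the sensitivities the backward sweep consumes: per-spike dl/dt_post terms
for spike-time losses, and a schedule of lambda_V jumps for voltage
losses that sample the membrane potential at discrete times via a Dirac
delta.  Batch averaging (the 1/N_batch factor) lives inside the heads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adjoint import LossSensitivities
from .network import NetworkConfig, SpikeRecord, Trajectory

__all__ = [
    "TTFSLossConfig",
    "MaxVoltageLossConfig",
    "FirstSpikeTable",
    "first_spike_times",
    "ttfs_loss",
    "TTFSLossHead",
    "voltage_max",
    "max_voltage_loss",
    "MaxVoltageLossHead",
    "SpikeTimeWeightedLoss",
]

MISSING = np.inf  # sentinel for "neuron never fired"


@dataclass
class TTFSLossConfig:
    """Hyperparameters of the time-to-first-spike cross-entropy.

    ``tau0`` scales the softmax over negative first spike times, ``tau1``
    and ``alpha`` the exponential regulariser that pushes the label
    neuron's spike early.  ``missing_penalty`` is the constant added to
    the *reported* loss for a sample whose label neuron stays silent;
    such samples carry no spike to differentiate through and contribute
    zero gradient.
    """

    output_neurons: tuple[int, ...]
    tau0: float = 0.5
    tau1: float = 6.4
    alpha: float = 3e-3
    missing_penalty: float = 100.0

    def __post_init__(self) -> None:
        if self.tau0 <= 0 or self.tau1 <= 0:
            raise ValueError("tau0 and tau1 must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        self.output_neurons = tuple(int(n) for n in self.output_neurons)


@dataclass
class MaxVoltageLossConfig:
    """Readout assignment for the max-over-time voltage cross-entropy;
    every listed neuron must be a non-firing leaky integrator."""

    readout_neurons: tuple[int, ...]

    def __post_init__(self) -> None:
        self.readout_neurons = tuple(int(n) for n in self.readout_neurons)


@dataclass
class FirstSpikeTable:
    """First spike per listed output neuron: time (``inf`` = missing) and
    the index of that spike in the record (-1 = missing)."""

    times: np.ndarray
    event_indices: np.ndarray


def first_spike_times(record: SpikeRecord,
                      cfg: TTFSLossConfig) -> FirstSpikeTable:
    """Earliest spike per output neuron, or MISSING if it never fired."""
    times = np.full(len(cfg.output_neurons), MISSING)
    idx = np.full(len(cfg.output_neurons), -1, dtype=int)
    pos = {n: j for j, n in enumerate(cfg.output_neurons)}
    for k, ev in enumerate(record.events):
        j = pos.get(ev.neuron)
        if j is not None and ev.time < times[j]:
            times[j] = ev.time
            idx[j] = k
    return FirstSpikeTable(times=times, event_indices=idx)


def _softmax_neg_times(times: np.ndarray, tau0: float) -> np.ndarray:
    """softmax(-t/tau0); missing times (inf) get probability zero."""
    z = -times / tau0
    z = z - np.max(z[np.isfinite(z)]) if np.any(np.isfinite(z)) else z
    p = np.where(np.isfinite(z), np.exp(z), 0.0)
    total = p.sum()
    return p / total if total > 0 else p


def ttfs_loss(table: FirstSpikeTable, label: int, cfg: TTFSLossConfig,
              batch_size: int = 1) -> tuple[float, LossSensitivities]:
    """Cross-entropy over the softmax of negative first spike times plus
    an exponential early-spiking regulariser, for one sample.

    loss = [-log softmax(-t/tau0)[label]
            + alpha (exp(t_label/tau1) - 1)] / N_batch

    Sensitivities carry dl/dt only for each output neuron's *first* spike
    (later spikes of the same neuron do not enter the loss).  A silent
    label neuron yields ``missing_penalty / N_batch`` and no gradient.
    """
    t = table.times
    p = _softmax_neg_times(t, cfg.tau0)
    sens = LossSensitivities()
    if not np.isfinite(t[label]):
        return cfg.missing_penalty / batch_size, sens
    ce = -float(np.log(p[label]))
    reg = cfg.alpha * (np.exp(t[label] / cfg.tau1) - 1.0)
    loss = (ce + reg) / batch_size
    for j, (tj, k) in enumerate(zip(t, table.event_indices)):
        if not np.isfinite(tj):
            continue
        g = ((1.0 if j == label else 0.0) - p[j]) / cfg.tau0
        if j == label:
            g += cfg.alpha / cfg.tau1 * np.exp(tj / cfg.tau1)
        sens.dlp_dtpost[int(k)] = sens.dlp_dtpost.get(int(k), 0.0) \
            + g / batch_size
    return loss, sens


def voltage_max(traj: Trajectory, neuron: int) -> tuple[float, float]:
    """Global maximum of the closed-form membrane potential over [0, T].

    Each inter-event segment is a double exponential whose interior
    extremum is analytic; the segment maximum is the larger of the
    endpoints and any interior extremum, and the global maximum the
    largest over segments (earliest time on exact ties).
    """
    tm, ts = traj.tau_mem, traj.tau_syn
    best_t, best_v = 0.0, -np.inf
    for seg in traj.segments:
        length = seg.t_end - seg.t_start
        v0 = seg.v_start[neuron]
        i0 = seg.i_start[neuron]
        a = i0 * ts / (ts - tm)
        cands = [0.0, length]
        # V'(d) = 0  =>  exp(d(1/ts - 1/tm)) = -a*tm / (ts*(v0 - a))
        denom = ts * (v0 - a)
        if denom != 0:
            ratio = -a * tm / denom
            if ratio > 0:
                d_star = np.log(ratio) / (1.0 / ts - 1.0 / tm)
                if 0.0 < d_star < length:
                    cands.append(d_star)
        for d in cands:
            v = (v0 - a) * np.exp(-d / tm) + a * np.exp(-d / ts)
            if v > best_v:
                best_v, best_t = v, seg.t_start + d
    return best_t, float(best_v)


def max_voltage_loss(vmax: np.ndarray, t_star: np.ndarray, label: int,
                     cfg: MaxVoltageLossConfig,
                     batch_size: int = 1) -> tuple[float, LossSensitivities]:
    """Cross-entropy over the softmax of per-readout voltage maxima.

    Writing max_t V_k = integral of V_k(t) * delta(t - t*_k), the chain
    rule turns each readout's contribution into a single lambda_V jump at
    its own maximum time; terms with the distributional derivative of the
    delta vanish.  The backward-traversal jump magnitude is
    (1{k=label} - softmax_k) / (tau_mem * N_batch), i.e. minus the
    forward-time loss sensitivity dL/dV_k scaled by 1/tau_mem.  The
    magnitudes sum to zero across readouts.
    """
    z = vmax - np.max(vmax)
    p = np.exp(z)
    p /= p.sum()
    loss = -float(np.log(p[label])) / batch_size
    sens = LossSensitivities()
    for k, neuron in enumerate(cfg.readout_neurons):
        mag = ((1.0 if k == label else 0.0) - p[k]) / batch_size
        sens.voltage_jumps.append((float(t_star[k]), neuron, mag))
    return loss, sens


@dataclass
class TTFSLossHead:
    """Bindable head: first-spike-time cross-entropy for one sample."""

    cfg: TTFSLossConfig
    label: int
    batch_size: int = 1

    def evaluate(self, record: SpikeRecord, traj: Trajectory,
                 config: NetworkConfig):
        table = first_spike_times(record, self.cfg)
        return ttfs_loss(table, self.label, self.cfg, self.batch_size)

    def predict(self, record: SpikeRecord) -> int:
        """Class of the earliest output spike; ties and the all-silent
        case fall back to the lowest class index."""
        table = first_spike_times(record, self.cfg)
        return int(np.argmin(table.times))  # argmin of all-inf is 0


@dataclass
class MaxVoltageLossHead:
    """Bindable head: max-over-time voltage cross-entropy for one sample."""

    cfg: MaxVoltageLossConfig
    label: int
    batch_size: int = 1

    def evaluate(self, record: SpikeRecord, traj: Trajectory,
                 config: NetworkConfig):
        if np.any(config.firing_mask[list(self.cfg.readout_neurons)]):
            raise ValueError("max-voltage readout neurons must be non-firing")
        t_star = np.empty(len(self.cfg.readout_neurons))
        vmax = np.empty_like(t_star)
        for k, neuron in enumerate(self.cfg.readout_neurons):
            t_star[k], vmax[k] = voltage_max(traj, neuron)
        loss, sens = max_voltage_loss(vmax, t_star, self.label, self.cfg,
                                      self.batch_size)
        # rescale jump magnitudes by 1/tau_mem here, where tau_mem is known
        sens.voltage_jumps = [
            (t, n, m / config.tau_mem) for t, n, m in sens.voltage_jumps]
        return loss, sens

    def predict(self, traj: Trajectory) -> int:
        vmax = [voltage_max(traj, n)[1] for n in self.cfg.readout_neurons]
        return int(np.argmax(vmax))


@dataclass
class SpikeTimeWeightedLoss:
    """Diagnostic loss: weighted sum of all spike times, per neuron.

    ``l = sum_k c[n(k)] * t_k``; used by the gradient-check experiment
    (all weight on one observed neuron) and by randomised oracle tests.
    """

    weights: dict[int, float] = field(default_factory=dict)

    def evaluate(self, record: SpikeRecord, traj: Trajectory,
                 config: NetworkConfig):
        sens = LossSensitivities()
        loss = 0.0
        for k, ev in enumerate(record.events):
            c = self.weights.get(ev.neuron, 0.0)
            if c != 0.0:
                loss += c * ev.time
                sens.dlp_dtpost[k] = c
        return loss, sens
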