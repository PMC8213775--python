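"""Reverse-time adjoint pass and exact weight gradients.

The adjoint spiking network pairs each state variable with a Lagrange
multiplier, (V, I) -> (lambda_V, lambda_I), integrated from t = T back to
t = 0 with boundary condition lambda_V(T) = lambda_I(T) = 0.  Between
events the adjoint dynamics are linear,

    tau_mem lambda_V' = -lambda_V          (voltage losses enter as jumps)
    tau_syn lambda_I' = -lambda_I + lambda_V

with ' the reverse-time derivative.  At the k-th recorded spike, caused by
neuron n(k), only that neuron's lambda_V jumps:

    lam_V-[n] = lam_V+[n] + (theta*lam_V+[n]
                + (W^T (lam_V+ - lam_I))[n] + dl_p/dt_k) / (tau_mem*vdot-)

while lambda_I and all other lambda_V components are continuous.  The
gradient for weight w_ji samples -tau_syn * lambda_I[j] whenever a spike
is transmitted from i to j; input weights sample the receiving neuron's
lambda_I at the fixed input spike times.  The backward sweep is a reverse
traversal of the merged forward event queue and touches only the spike
record and the loss jump schedule, never a dense state history, so memory
scales with the number of spikes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .forward import CriticalPointWarning
from .network import InputSpikeTrain, NetworkConfig, SpikeRecord

log = logging.getLogger(__name__)

__all__ = [
    "AdjointState",
    "LossSensitivities",
    "GradientAccumulator",
    "adjoint_evolve_free",
    "apply_adjoint_spike_jump",
    "apply_voltage_loss_jump",
    "accumulate_gradient",
    "eventprop_gradient",
]


@dataclass
class AdjointState:
    """Adjoint pair at forward time ``t``, evolved from T down to 0."""

    t: float
    lambda_v: np.ndarray
    lambda_i: np.ndarray

    @classmethod
    def terminal(cls, n: int, t_end: float) -> "AdjointState":
        """Boundary condition lambda_V(T) = lambda_I(T) = 0."""
        return cls(t=t_end, lambda_v=np.zeros(n), lambda_i=np.zeros(n))

    def copy(self) -> "AdjointState":
        return AdjointState(self.t, self.lambda_v.copy(), self.lambda_i.copy())


@dataclass
class LossSensitivities:
    """What a loss head hands to the backward pass.

    Attributes
    ----------
    dlp_dtpost
        Map from spike-record index k to dl_p/dt_post_k (1/ms); only the
        spikes a loss actually depends on appear (e.g. first spikes).
    voltage_jumps
        Schedule of (time, neuron, magnitude) jumps added to lambda_V
        during the backward sweep; used by voltage-sampling losses.
    lv_discontinuities
        Per spike index, (l_V-, l_V+) at the transition.  Zero for both
        published loss heads (voltage losses here only touch non-firing
        readouts, where l_V is continuous across network spikes).
    """

    dlp_dtpost: dict[int, float] = field(default_factory=dict)
    voltage_jumps: list[tuple[float, int, float]] = field(default_factory=list)
    lv_discontinuities: dict[int, tuple[float, float]] = field(
        default_factory=dict)


@dataclass
class GradientAccumulator:
    """Per-weight gradient sums, shaped like the weight matrices."""

    g_rec: np.ndarray
    g_in: np.ndarray

    @classmethod
    def zeros(cls, config: NetworkConfig) -> "GradientAccumulator":
        return cls(g_rec=np.zeros_like(config.w_rec),
                   g_in=np.zeros_like(config.w_in))


def adjoint_evolve_free(adj: AdjointState, dt: float,
                        config: NetworkConfig) -> AdjointState:
    """Advance the adjoint pair backward by ``dt`` (forward-time ms)
    using the closed-form solution of the linear reverse-time system."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if config.tau_mem == config.tau_syn:
        raise ValueError("tau_mem == tau_syn unsupported")
    if dt == 0:
        return adj.copy()
    tm, ts = config.tau_mem, config.tau_syn
    b = adj.lambda_v * tm / (tm - ts)
    em = np.exp(-dt / tm)
    es = np.exp(-dt / ts)
    return AdjointState(
        t=adj.t - dt,
        lambda_v=adj.lambda_v * em,
        lambda_i=(adj.lambda_i - b) * es + b * em,
    )


def apply_adjoint_spike_jump(adj: AdjointState, event, sens: LossSensitivities,
                             config: NetworkConfig,
                             event_index: int | None = None) -> AdjointState:
    """Apply the adjoint jump of one recorded spike (backward traversal).

    Only the firing neuron's lambda_V component jumps; lambda_I and the
    other lambda_V components are continuous.  Uses the pre-reset membrane
    slope cached in the forward pass.
    """
    vdot = event.vdot_minus
    if abs(vdot) < config.eps_crit:
        warnings.warn(
            f"adjoint jump at t={event.time:.6f} ms, neuron {event.neuron}: "
            f"|dV/dt|={abs(vdot):.3e} below eps_crit, gradient diverges",
            CriticalPointWarning,
            stacklevel=2,
        )
    n = event.neuron
    dlp = sens.dlp_dtpost.get(event_index, 0.0) if event_index is not None \
        else 0.0
    lv_minus, lv_plus = sens.lv_discontinuities.get(
        event_index, (0.0, 0.0)) if event_index is not None else (0.0, 0.0)
    err = adj.lambda_v - adj.lambda_i
    bracket = (config.threshold * adj.lambda_v[n]
               + float(config.w_rec[:, n] @ err)  # (W^T err)[n]
               + dlp + lv_minus - lv_plus)
    out = adj.copy()
    out.lambda_v[n] += bracket / (config.tau_mem * vdot)
    return out


def apply_voltage_loss_jump(adj: AdjointState, neuron: int,
                            magnitude: float) -> AdjointState:
    """Add a scheduled voltage-loss jump to one lambda_V component."""
    out = adj.copy()
    out.lambda_v[neuron] += magnitude
    return out


def accumulate_gradient(acc: GradientAccumulator, event,
                        adj: AdjointState,
                        config: NetworkConfig) -> GradientAccumulator:
    """Accumulate -tau_syn * lambda_I at one transmitted spike.

    ``event`` is either a recorded recurrent spike (``SpikeEvent``) or a
    tuple ``("input", channel)`` for a fixed input spike; ``adj`` must
    hold the adjoint state at the event time.
    """
    contrib = config.tau_syn * adj.lambda_i
    if isinstance(event, tuple) and event[0] == "input":
        acc.g_in[:, event[1]] -= contrib
    else:
        i = event.neuron
        col = contrib.copy()
        col[i] = 0.0  # no self-connections
        acc.g_rec[:, i] -= col
    return acc


def _merged_backward_queue(record: SpikeRecord, inputs: InputSpikeTrain,
                           sens: LossSensitivities):
    """Merged event queue grouped by time, ordered for reverse traversal.

    Within one (numerically identical) time the backward processing order
    is: voltage-loss jumps, then recurrent-spike jumps (each computed from
    the common pre-jump adjoint state), then input spikes — the mirror of
    the forward inputs-first rule.
    """
    entries = []
    for k, ev in enumerate(record.events):
        entries.append((ev.time, 1, ("spike", k)))
    for j, (t, c) in enumerate(zip(inputs.times, inputs.channels)):
        entries.append((float(t), 2, ("input", int(c))))
    for t, neuron, mag in sens.voltage_jumps:
        entries.append((float(t), 0, ("vjump", neuron, mag)))
    entries.sort(key=lambda e: (e[0], e[1]))

    groups: list[tuple[float, list]] = []
    for t, _, payload in entries:
        if groups and groups[-1][0] == t:
            groups[-1][1].append(payload)
        else:
            groups.append((t, [payload]))
    return groups


def eventprop_gradient(config: NetworkConfig, inputs: InputSpikeTrain,
                       loss_head) -> tuple[float, GradientAccumulator]:
    """Full forward + backward pass: loss value and exact weight gradient.

    Runs the event-driven forward pass, evaluates ``loss_head`` on the
    spike record and trajectory, then sweeps the merged event queue in
    reverse, interleaving free adjoint evolution, loss jumps, spike jumps
    and gradient accumulation.
    """
    from .forward import simulate

    record, traj = simulate(config, inputs)
    loss, sens = loss_head.evaluate(record, traj, config)
    acc = backward_sweep(config, inputs, record, sens)
    if log.isEnabledFor(logging.DEBUG):
        min_vdot = min((abs(e.vdot_minus) for e in record.events),
                       default=float("inf"))
        log.debug("eventprop_gradient: spikes=%d min|vdot-|=%.3e loss=%.6g",
                  len(record), min_vdot, loss)
    return loss, acc


def backward_sweep(config: NetworkConfig, inputs: InputSpikeTrain,
                   record: SpikeRecord,
                   sens: LossSensitivities) -> GradientAccumulator:
    """Reverse traversal of the merged event queue (Algorithm backward
    half): returns the accumulated gradient."""
    adj = AdjointState.terminal(config.n_neurons, config.t_end)
    acc = GradientAccumulator.zeros(config)
    groups = _merged_backward_queue(record, inputs, sens)

    for t, payloads in reversed(groups):
        if t > config.t_end:
            continue
        adj = adjoint_evolve_free(adj, adj.t - t, config)
        # 1) scheduled voltage-loss jumps
        for p in payloads:
            if p[0] == "vjump":
                adj = apply_voltage_loss_jump(adj, p[1], p[2])
        # 2) recurrent spikes: gradient accumulation (lambda_I is
        #    continuous across jumps) and adjoint jumps, each from the
        #    common pre-jump state (coincident-spike rule)
        spike_payloads = [p for p in payloads if p[0] == "spike"]
        for _, k in spike_payloads:
            acc = accumulate_gradient(acc, record.events[k], adj, config)
        if spike_payloads:
            pre = adj
            out = pre.copy()
            for _, k in spike_payloads:
                ev = record.events[k]
                jumped = apply_adjoint_spike_jump(pre, ev, sens, config,
                                                 event_index=k)
                out.lambda_v[ev.neuron] = jumped.lambda_v[ev.neuron]
            adj = out
        # 3) input spikes
        for p in payloads:
            if p[0] == "input":
                acc = accumulate_gradient(acc, ("input", p[1]), adj, config)
    return acc
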