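"""Independent verification machinery.

Three mutually independent routes cross-check the event-driven simulator
and adjoint gradient: central finite differences through full forward
simulations, a dense explicit-Euler discretisation of the network, and a
closed-form bouncing-ball hybrid system whose sensitivity jumps across
impacts are known analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import simulate
from .network import InputSpikeTrain, NetworkConfig, SpikeEvent, SpikeRecord

__all__ = [
    "FiniteDiffSpec",
    "central_difference_gradient",
    "euler_forward",
    "simulate_ball",
    "BallSensitivity",
]


@dataclass
class FiniteDiffSpec:
    """Central-difference settings.

    ``epsilon`` scales with the weight magnitude (``eps = epsilon *
    max(|w|, 1)``).  With the spike-count guard on, a perturbed run whose
    per-neuron spike counts differ from the base run marks the entry
    CRITICAL: a spike appeared or vanished between the two evaluations,
    the implicit-function-theorem premise fails, and the difference
    quotient is meaningless there.
    """

    epsilon: float = 1e-4
    guard_spike_count: bool = True


def _spike_signature(record: SpikeRecord, n: int) -> tuple:
    counts = np.zeros(n, dtype=int)
    for ev in record.events:
        counts[ev.neuron] += 1
    return tuple(counts)


def _loss_of(config: NetworkConfig, inputs: InputSpikeTrain, loss_head):
    record, traj = simulate(config, inputs)
    loss, _ = loss_head.evaluate(record, traj, config)
    return loss, _spike_signature(record, config.n_neurons)


def central_difference_gradient(config: NetworkConfig,
                                inputs: InputSpikeTrain, loss_head,
                                entries: list[tuple[str, int, int]],
                                spec: FiniteDiffSpec | None = None):
    """Central-difference loss gradient for selected weights.

    ``entries`` lists weights as ``("rec", j, i)`` or ``("in", j, c)``.
    Returns ``(gradients, critical_flags)`` arrays; flagged entries had a
    spike-count change between the two perturbed runs and must be
    excluded from comparisons.
    """
    spec = spec or FiniteDiffSpec()
    base_sig = None
    if spec.guard_spike_count:
        _, base_sig = _loss_of(config, inputs, loss_head)
    grads = np.empty(len(entries))
    critical = np.zeros(len(entries), dtype=bool)
    for idx, (kind, j, i) in enumerate(entries):
        w = config.w_rec if kind == "rec" else config.w_in
        eps = spec.epsilon * max(abs(w[j, i]), 1.0)
        losses = []
        sigs = []
        for sign in (+1.0, -1.0):
            w_pert = w.copy()
            w_pert[j, i] += sign * eps
            cfg = config.with_weights(w_rec=w_pert) if kind == "rec" \
                else config.with_weights(w_in=w_pert)
            loss, sig = _loss_of(cfg, inputs, loss_head)
            losses.append(loss)
            sigs.append(sig)
        grads[idx] = (losses[0] - losses[1]) / (2.0 * eps)
        if spec.guard_spike_count and not (sigs[0] == sigs[1] == base_sig):
            critical[idx] = True
    return grads, critical


def richardson_gradient(config: NetworkConfig, inputs: InputSpikeTrain,
                        loss_head, entries: list[tuple[str, int, int]],
                        epsilon: float = 1e-3):
    """Richardson-extrapolated central differences.

    Combines quotients at ``epsilon`` and ``epsilon/2`` as
    ``(4 F(eps/2) - F(eps)) / 3``, cancelling the O(eps^2) truncation
    term.  The larger admissible step keeps the rounding noise of the
    loss evaluation well below the quotient, which plain central
    differences cannot achieve for small-magnitude gradient entries.
    Critical flags are the union over both step sizes.
    """
    fd1, c1 = central_difference_gradient(config, inputs, loss_head,
                                          entries,
                                          FiniteDiffSpec(epsilon=epsilon))
    fd2, c2 = central_difference_gradient(
        config, inputs, loss_head, entries,
        FiniteDiffSpec(epsilon=epsilon / 2.0))
    return (4.0 * fd2 - fd1) / 3.0, c1 | c2


def euler_forward(config: NetworkConfig, inputs: InputSpikeTrain,
                  dt: float) -> SpikeRecord:
    """Explicit-Euler discretisation of the LIF network.

    Independent of the event-driven path: fixed step, threshold test per
    step, reset and recurrent current jumps applied at the step where the
    threshold is exceeded.  Spike times converge linearly in ``dt`` to
    the event-driven ones.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = config.n_neurons
    v = np.zeros(n)
    i = np.zeros(n)
    record = SpikeRecord()
    n_steps = int(np.ceil(config.t_end / dt))
    in_times = inputs.times
    in_channels = inputs.channels
    ptr = 0
    for step in range(n_steps):
        t = step * dt
        while ptr < len(in_times) and in_times[ptr] <= t:
            i = i + config.w_in[:, in_channels[ptr]]
            ptr += 1
        dv = (-v + i) / config.tau_mem
        di = -i / config.tau_syn
        v = v + dt * dv
        i = i + dt * di
        fired = np.flatnonzero(config.firing_mask
                               & (v >= config.threshold))
        for m in fired:
            record.events.append(SpikeEvent(
                time=t + dt, neuron=int(m), i_minus=float(i[m]),
                vdot_minus=float((-config.threshold + i[m])
                                 / config.tau_mem)))
            v[m] = 0.0
            i = i + config.w_rec[:, m]
    return record


@dataclass
class BallSensitivity:
    """Sensitivities of the bouncing ball around one ground impact."""

    t_impact: float
    dy_dy0_before: float
    dy_dy0_after: float
    dv_dy0_before: float
    dv_dy0_after: float
    dt_impact_dy0: float
    v_minus: float


def _ball_flight(y0: float, v0: float, g: float, t: np.ndarray):
    """Closed-form ballistic flight from (y0, v0)."""
    return y0 + v0 * t - 0.5 * g * t * t, v0 - g * t


def _first_impact_time(y0: float, v0: float, g: float) -> float:
    """Positive root of y0 + v0 t - g t^2/2 = 0."""
    disc = v0 * v0 + 2.0 * g * y0
    return (v0 + np.sqrt(disc)) / g


def simulate_ball(y0: float, g: float = 9.81, n_bounces: int = 3,
                  restitution: float = 0.8, eps: float = 1e-6):
    """Inelastic bouncing ball with finite-difference sensitivities.

    The ball falls under gravity from rest at height ``y0`` and reflects
    as ``v+ = -restitution * v-`` at each ground impact.  Flight between
    impacts is closed form and impact times are solved exactly.  The
    sensitivities d y/d y0 and d v/d y0 just before and after each impact
    are estimated by central differences in ``y0``, giving the jump
    ratios the hybrid-system theory predicts:

        dy+/dy0 = -restitution * dy-/dy0
        dv+/dy0 = -restitution * dv-/dy0 - (1+restitution) g (1/v-) dy-/dy0
        dt_impact/dy0 = -(1/v-) * dy-/dy0

    Returns a list of ``BallSensitivity``, one per impact.
    """
    if y0 <= 0:
        raise ValueError("y0 must be positive")

    def impact_states(y0_val: float):
        """(t_r, y-, v-, y+, v+) for each of the first n_bounces impacts."""
        out = []
        t_abs, y, v = 0.0, y0_val, 0.0
        for _ in range(n_bounces):
            t_r = _first_impact_time(y, v, g)
            y_minus, v_minus = _ball_flight(y, v, g, np.array([t_r]))
            y_minus, v_minus = float(y_minus[0]), float(v_minus[0])
            t_abs += t_r
            v_plus = -restitution * v_minus
            out.append((t_abs, y_minus, v_minus, 0.0, v_plus))
            y, v = 0.0, v_plus
        return out

    base = impact_states(y0)
    hi = impact_states(y0 + eps)
    lo = impact_states(y0 - eps)

    results = []
    for k, (t_r, _, v_minus, _, _) in enumerate(base):
        # sensitivities at fixed time just before/after the impact: evaluate
        # the perturbed trajectories at the *base* impact time
        dt_small = min(1e-3, t_r * 0.01)
        t_before = t_r - dt_small
        t_after = t_r + dt_small

        def y_v_at(states, y0_val, t_query):
            """(y, v) of a perturbed trajectory at absolute time t_query."""
            t_prev, y, v = 0.0, y0_val, 0.0
            for (t_i, _, _, y_p, v_p) in states:
                if t_query < t_i:
                    break
                t_prev, y, v = t_i, y_p, v_p
            yq, vq = _ball_flight(y, v, g, np.array([t_query - t_prev]))
            return float(yq[0]), float(vq[0])

        y_hi_b, v_hi_b = y_v_at(hi, y0 + eps, t_before)
        y_lo_b, v_lo_b = y_v_at(lo, y0 - eps, t_before)
        y_hi_a, v_hi_a = y_v_at(hi, y0 + eps, t_after)
        y_lo_a, v_lo_a = y_v_at(lo, y0 - eps, t_after)

        # extrapolate the one-sided sensitivities to the impact time by
        # shrinking dt_small's effect: the flight is smooth, so the
        # finite-difference at t_r -/+ dt_small differs from the limit by
        # O(dt_small); evaluate at two offsets and Richardson-extrapolate
        def sens(t_q):
            y_h, v_h = y_v_at(hi, y0 + eps, t_q)
            y_l, v_l = y_v_at(lo, y0 - eps, t_q)
            return (y_h - y_l) / (2 * eps), (v_h - v_l) / (2 * eps)

        d1y_b, d1v_b = sens(t_r - dt_small)
        d2y_b, d2v_b = sens(t_r - dt_small / 2)
        dy_b = 2 * d2y_b - d1y_b
        dv_b = 2 * d2v_b - d1v_b
        d1y_a, d1v_a = sens(t_r + dt_small)
        d2y_a, d2v_a = sens(t_r + dt_small / 2)
        dy_a = 2 * d2y_a - d1y_a
        dv_a = 2 * d2v_a - d1v_a

        dt_dy0 = (hi[k][0] - lo[k][0]) / (2 * eps)
        results.append(BallSensitivity(
            t_impact=t_r, dy_dy0_before=dy_b, dy_dy0_after=dy_a,
            dv_dy0_before=dv_b, dv_dy0_after=dv_a,
            dt_impact_dy0=dt_dy0, v_minus=v_minus))
    return results
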