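"""Event-driven forward pass: exact integration between events, root
bracketing for threshold crossings, and the discrete jumps at spikes.

Between events the LIF free dynamics are linear and solved in closed form,

    I(t0 + d) = I0 exp(-d/tau_syn),
    V(t0 + d) = (V0 - A) exp(-d/tau_mem) + A exp(-d/tau_syn),
    A = I0 * tau_syn / (tau_syn - tau_mem),

so simulation advances from event to event with no time-stepping error.
Threshold crossings are located by scanning the closed form on a grid finer
than the smallest time constant and refining the bracketed sign change by
bisection.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from scipy.optimize import brentq

from .network import (
    InputSpikeTrain,
    NetworkConfig,
    NeuronState,
    SpikeEvent,
    SpikeRecord,
    Trajectory,
    TrajectorySegment,
)

log = logging.getLogger(__name__)

__all__ = [
    "free_solution",
    "evolve_free",
    "next_threshold_crossing",
    "apply_spike_transition",
    "apply_input_spike",
    "simulate",
    "CriticalPointWarning",
]

#: absolute tolerance (in threshold units) within which V counts as "at
#: threshold" when collecting coincident crossings
CROSSING_TOL = 1e-9

#: bisection iterations; from a tau_syn/20 bracket this resolves event
#: times to far below 1e-12 ms
_BISECT_ITERS = 70


class CriticalPointWarning(UserWarning):
    """A spike occurred with near-zero membrane slope; the exact gradient
    diverges at such critical points."""


def free_solution(v0, i0, dt, tau_mem, tau_syn):
    """Closed-form free evolution by ``dt >= 0``; works on vectors."""
    if np.ndim(dt) == 0 and dt == 0:
        return np.asarray(v0).copy(), np.asarray(i0).copy()
    a = np.asarray(i0) * tau_syn / (tau_syn - tau_mem)
    em = np.exp(-dt / tau_mem)
    es = np.exp(-dt / tau_syn)
    v = (np.asarray(v0) - a) * em + a * es
    return v, np.asarray(i0) * es


def evolve_free(state: NeuronState, dt: float, config: NetworkConfig) -> NeuronState:
    """Advance the state by ``dt`` under the spike-free dynamics."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    v, i = free_solution(state.v, state.i, dt, config.tau_mem, config.tau_syn)
    return NeuronState(t=state.t + dt, v=v, i=i)


def membrane_slope(v, i, tau_mem):
    """dV/dt = (-V + I) / tau_mem."""
    return (-np.asarray(v) + np.asarray(i)) / tau_mem


def _bisect_crossing(v0: float, i0: float, d_lo: float, d_hi: float,
                     theta: float, tau_mem: float, tau_syn: float) -> float:
    """Refine an upward threshold crossing bracketed in (d_lo, d_hi]."""
    a = i0 * tau_syn / (tau_syn - tau_mem)
    b = v0 - a

    def f(d: float) -> float:
        return b * math.exp(-d / tau_mem) + a * math.exp(-d / tau_syn) - theta

    f_lo = f(d_lo)
    if f_lo > 0:  # left edge already above threshold (coincidence corner)
        return d_lo
    try:
        return float(brentq(f, d_lo, d_hi, xtol=1e-14, rtol=8.9e-16,
                            maxiter=200))
    except ValueError:
        # no sign change at the edges (grazing numerical corner): fall
        # back to plain bisection on the midpoint predicate
        for _ in range(_BISECT_ITERS):
            mid = 0.5 * (d_lo + d_hi)
            if mid == d_lo or mid == d_hi:
                break
            if f(mid) > 0:
                d_hi = mid
            else:
                d_lo = mid
        return d_hi


def next_threshold_crossing(state: NeuronState, horizon: float,
                            config: NetworkConfig):
    """Earliest upward threshold crossing of any firing neuron in
    ``(state.t, horizon]``.

    Returns ``(time, neuron)`` or ``None``.  A crossing is declared only
    on a sign change of ``V - theta`` on the scan grid, so a membrane
    potential peaking tangentially at the threshold (the measure-zero
    critical set, where the transition condition dV/dt != 0 fails anyway)
    does not trigger a spike.
    """
    window = horizon - state.t
    if window <= 0 or not np.any(config.firing_mask):
        return None
    step = config.tau_syn / 20.0
    n_steps = max(1, int(np.ceil(window / step)))
    d = np.linspace(0.0, window, n_steps + 1)

    idx = np.flatnonzero(config.firing_mask)
    v0 = state.v[idx]
    i0 = state.i[idx]
    a = i0 * config.tau_syn / (config.tau_syn - config.tau_mem)
    em = np.exp(-d[:, None] / config.tau_mem)
    es = np.exp(-d[:, None] / config.tau_syn)
    f = (v0 - a) * em + a * es - config.threshold  # (grid, neurons)

    above = f > 0
    # first grid cell per neuron with f[k] <= 0 < f[k+1]
    up = ~above[:-1] & above[1:]
    cols = np.flatnonzero(up.any(axis=0))
    if len(cols) == 0:
        return None
    first_cell = np.array([np.argmax(up[:, c]) for c in cols])
    # only neurons whose first sign change lies in the earliest cell can
    # host the earliest crossing
    k_min = int(first_cell.min())
    best_t, best_n = np.inf, -1
    for col, k in zip(cols, first_cell):
        if k != k_min:
            continue
        d_star = _bisect_crossing(v0[col], i0[col], d[k], d[k + 1],
                                  config.threshold, config.tau_mem,
                                  config.tau_syn)
        t_star = state.t + d_star
        if t_star < best_t:
            best_t, best_n = t_star, int(idx[col])
    return min(best_t, horizon), best_n


def apply_spike_transition(state: NeuronState, neuron: int,
                           config: NetworkConfig) -> NeuronState:
    """Reset the firing neuron and deliver its recurrent current jumps.

    ``V[neuron] -> 0`` and ``I += w_rec[:, neuron]``; all other membrane
    potentials are untouched.  Warns when the pre-reset slope is within
    ``eps_crit`` of zero (critical point: the adjoint jump would diverge).
    """
    vdot = membrane_slope(state.v[neuron], state.i[neuron], config.tau_mem)
    if abs(vdot) < config.eps_crit:
        warnings.warn(
            f"neuron {neuron} spiked with |dV/dt|={abs(vdot):.3e} < "
            f"eps_crit={config.eps_crit:.0e} at t={state.t:.6f} ms",
            CriticalPointWarning,
            stacklevel=2,
        )
    out = state.copy()
    out.v[neuron] = 0.0
    out.i += config.w_rec[:, neuron]
    return out


def apply_input_spike(state: NeuronState, channel: int,
                      config: NetworkConfig) -> NeuronState:
    """Deliver one fixed input spike: ``I += w_in[:, channel]``."""
    out = state.copy()
    out.i += config.w_in[:, channel]
    return out


def simulate(config: NetworkConfig,
             inputs: InputSpikeTrain) -> tuple[SpikeRecord, Trajectory]:
    """Run the event-driven forward pass from V = I = 0 at t = 0 to T.

    A merged queue of fixed input spikes and detected threshold crossings
    is processed in time order.  At numerically equal times input spikes
    are applied first, then threshold crossings (current jumps commute, so
    the state is order-independent; the rule only fixes replay order).
    Every recorded spike caches the firing neuron's pre-reset current and
    membrane slope for the backward pass.

    Returns the spike record and a piecewise closed-form trajectory.
    """
    n = config.n_neurons
    state = NeuronState.zero(n)
    record = SpikeRecord()
    traj = Trajectory(tau_mem=config.tau_mem, tau_syn=config.tau_syn)
    t_end = config.t_end

    in_times = inputs.times
    in_channels = inputs.channels
    ptr = 0
    n_in = len(in_times)
    seg_start = state.copy()

    def close_segment(t_event: float) -> None:
        traj.segments.append(TrajectorySegment(
            t_start=seg_start.t, t_end=t_event,
            v_start=seg_start.v.copy(), i_start=seg_start.i.copy()))

    while state.t < t_end:
        t_next_input = in_times[ptr] if ptr < n_in else np.inf
        horizon = min(t_next_input, t_end)
        crossing = next_threshold_crossing(state, horizon, config)

        if crossing is not None and crossing[0] < t_next_input:
            t_star = crossing[0]
            state = evolve_free(state, t_star - state.t, config)
            close_segment(t_star)
            # collect every firing neuron at threshold with positive slope
            # (coincident spikes) using the pre-transition state
            vdot = membrane_slope(state.v, state.i, config.tau_mem)
            at_theta = (config.firing_mask
                        & (np.abs(state.v - config.threshold) <= CROSSING_TOL)
                        & (vdot > 0))
            spiking = np.flatnonzero(at_theta)
            if len(spiking) == 0:  # numerical corner: fall back to finder
                spiking = np.array([crossing[1]])
            for m in spiking:
                record.events.append(SpikeEvent(
                    time=t_star, neuron=int(m),
                    i_minus=float(state.i[m]),
                    vdot_minus=float(vdot[m])))
            if len(record) > config.spike_cap:
                raise RuntimeError(
                    f"spike cap exceeded ({config.spike_cap} events): "
                    "runaway network activity")
            for m in spiking:
                state = apply_spike_transition(state, int(m), config)
            seg_start = state.copy()
        else:
            # advance to the next input event (or to T)
            state = evolve_free(state, horizon - state.t, config)
            if ptr < n_in and horizon == t_next_input:
                close_segment(horizon)
                while ptr < n_in and in_times[ptr] == t_next_input:
                    state = apply_input_spike(state, int(in_channels[ptr]),
                                              config)
                    ptr += 1
                seg_start = state.copy()
            else:
                break

    close_segment(t_end)
    return record, traj
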