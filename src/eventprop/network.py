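"""Core containers for event-driven LIF network simulation.

The neuron model is the standard current-based leaky integrate-and-fire
network with exponential synapses,

    tau_mem dV/dt = -V + I,     tau_syn dI/dt = -I,

where ``V`` and ``I`` are length-``N`` vectors.  When a firing neuron's
membrane potential reaches the threshold ``theta`` (with dV/dt != 0), its
potential is reset to zero and the synaptic currents of all neurons jump by
the corresponding column of the recurrent weight matrix.  Voltages are
measured in units of the threshold, times in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkConfig",
    "NeuronState",
    "InputSpikeTrain",
    "SpikeEvent",
    "SpikeRecord",
    "TrajectorySegment",
    "Trajectory",
]


@dataclass
class NetworkConfig:
    """Parameters of a recurrent LIF network.

    Parameters
    ----------
    tau_mem, tau_syn
        Membrane and synaptic time constants in ms.  They must differ; the
        degenerate alpha-kernel case ``tau_mem == tau_syn`` is unsupported.
    threshold
        Firing threshold ``theta``; membrane potentials are expressed in
        units of it (default 1.0).
    w_rec
        ``N x N`` recurrent weight matrix with exactly zero diagonal
        (no self-connections).  ``w_rec[j, i]`` connects firing neuron
        ``i`` to receiving neuron ``j``.  Feed-forward architectures are
        block-structured special cases.
    w_in
        ``N x M`` input weight matrix; column ``c`` is added to ``I``
        whenever input channel ``c`` spikes.
    firing_mask
        Per-neuron boolean; ``False`` marks non-firing leaky-integrator
        readouts that never cross threshold (effectively infinite
        threshold).
    t_end
        Simulation horizon ``T`` in ms.
    spike_cap
        Runaway-activity guard: simulation aborts beyond this many spikes.
    eps_crit
        Threshold-crossing slope guard; crossings with ``|dV/dt| <
        eps_crit`` sit next to a critical point where the gradient
        diverges and are reported.
    """

    tau_mem: float
    tau_syn: float
    w_rec: np.ndarray
    w_in: np.ndarray
    threshold: float = 1.0
    firing_mask: np.ndarray | None = None
    t_end: float = 100.0
    spike_cap: int = 1_000_000
    eps_crit: float = 1e-8

    def __post_init__(self) -> None:
        if self.tau_mem <= 0 or self.tau_syn <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_mem == self.tau_syn:
            raise ValueError(
                "tau_mem == tau_syn (alpha kernel) is not supported by the "
                "closed-form integrator"
            )
        if self.t_end <= 0:
            raise ValueError("simulation horizon t_end must be positive")
        self.w_rec = np.ascontiguousarray(self.w_rec, dtype=float)
        self.w_in = np.ascontiguousarray(self.w_in, dtype=float)
        if self.w_rec.ndim != 2 or self.w_rec.shape[0] != self.w_rec.shape[1]:
            raise ValueError("w_rec must be a square matrix")
        if np.any(np.diag(self.w_rec) != 0.0):
            raise ValueError("w_rec must have an exactly zero diagonal")
        if self.w_in.ndim != 2 or self.w_in.shape[0] != self.n_neurons:
            raise ValueError("w_in must have shape (n_neurons, n_inputs)")
        if self.firing_mask is None:
            self.firing_mask = np.ones(self.n_neurons, dtype=bool)
        else:
            self.firing_mask = np.asarray(self.firing_mask, dtype=bool)
            if self.firing_mask.shape != (self.n_neurons,):
                raise ValueError("firing_mask must have length n_neurons")

    @property
    def n_neurons(self) -> int:
        return self.w_rec.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[1]

    def with_weights(self, w_rec: np.ndarray | None = None,
                     w_in: np.ndarray | None = None) -> "NetworkConfig":
        """Return a copy with replaced weight matrices."""
        return replace(
            self,
            w_rec=self.w_rec if w_rec is None else w_rec,
            w_in=self.w_in if w_in is None else w_in,
        )


@dataclass
class NeuronState:
    """Instantaneous network state: time plus the (V, I) vectors."""

    t: float
    v: np.ndarray
    i: np.ndarray

    @classmethod
    def zero(cls, n: int, t: float = 0.0) -> "NeuronState":
        return cls(t=t, v=np.zeros(n), i=np.zeros(n))

    def copy(self) -> "NeuronState":
        return NeuronState(t=self.t, v=self.v.copy(), i=self.i.copy())


@dataclass
class InputSpikeTrain:
    """Fixed pre-synaptic spike train: sorted (time, channel) events."""

    times: np.ndarray
    channels: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.channels = np.atleast_1d(np.asarray(self.channels, dtype=int))
        if self.times.shape != self.channels.shape:
            raise ValueError("times and channels must have equal length")
        if np.any(np.diff(self.times) < 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.channels = self.channels[order]

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def empty(cls) -> "InputSpikeTrain":
        return cls(np.empty(0), np.empty(0, dtype=int))

    @classmethod
    def from_pairs(cls, events) -> "InputSpikeTrain":
        if not events:
            return cls.empty()
        t, c = zip(*events)
        return cls(np.asarray(t, float), np.asarray(c, int))


@dataclass
class SpikeEvent:
    """One post-synaptic spike with the cached pre-reset quantities the
    backward pass needs: the firing neuron's synaptic current ``i_minus``
    just before reset and the membrane slope ``vdot_minus = (-theta +
    i_minus)/tau_mem``."""

    time: float
    neuron: int
    i_minus: float
    vdot_minus: float


@dataclass
class SpikeRecord:
    """Time-ordered list of post-synaptic spikes.

    This is the only forward-pass state the voltage-independent backward
    pass consumes, giving the O(S) memory footprint of the method.
    """

    events: list[SpikeEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])

    @property
    def neurons(self) -> np.ndarray:
        return np.array([e.neuron for e in self.events], dtype=int)

    def spikes_of(self, neuron: int) -> np.ndarray:
        """Sorted spike times of one neuron."""
        return np.array([e.time for e in self.events if e.neuron == neuron])


@dataclass
class TrajectorySegment:
    """Closed-form state over one inter-event interval [t_start, t_end]."""

    t_start: float
    t_end: float
    v_start: np.ndarray
    i_start: np.ndarray


@dataclass
class Trajectory:
    """Piecewise closed-form trajectory tiling [0, T].

    Segments store post-transition state at their left edge; evaluating a
    segment's closed form at ``t_end`` gives the pre-transition state of
    the next event.
    """

    segments: list[TrajectorySegment] = field(default_factory=list)
    tau_mem: float = 0.0
    tau_syn: float = 0.0

    def _locate(self, t: float) -> TrajectorySegment:
        # binary search over segment starts; right-continuous convention
        lo, hi = 0, len(self.segments) - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if self.segments[mid].t_start <= t:
                lo = mid
            else:
                hi = mid - 1
        return self.segments[lo]

    def state_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate (V, I) at forward time ``t`` (right-continuous at
        event times)."""
        from .forward import free_solution

        seg = self._locate(t)
        return free_solution(seg.v_start, seg.i_start, t - seg.t_start,
                             self.tau_mem, self.tau_syn)

    def sample(self, times: np.ndarray, neuron: int) -> np.ndarray:
        """Membrane potential of one neuron on a grid (for plotting and
        dense-scan verification)."""
        return np.array([self.state_at(t)[0][neuron] for t in times])
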