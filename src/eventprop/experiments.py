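"""Canonical experiment setups.

The two-neuron gradient-check benchmark: neuron A receives 100
independent Poisson spike trains at 200 Hz through randomly initialised
input weights and drives neuron B through a single feed-forward weight;
the loss is the sum of B's spike times.  The adjoint gradient for every
weight is compared against central differences through full
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .adjoint import eventprop_gradient
from .losses import SpikeTimeWeightedLoss
from .network import InputSpikeTrain, NetworkConfig
from .oracles import FiniteDiffSpec, central_difference_gradient

__all__ = [
    "poisson_input_train",
    "two_neuron_setup",
    "gradient_check_experiment",
    "GradCheckResult",
]


def poisson_input_train(n_channels: int, rate_hz: float, t_end: float,
                        rng: np.random.Generator) -> InputSpikeTrain:
    """Independent homogeneous Poisson spike trains on each channel."""
    rate_per_ms = rate_hz / 1000.0
    events = []
    for c in range(n_channels):
        t = rng.exponential(1.0 / rate_per_ms)
        while t <= t_end:
            events.append((t, c))
            t += rng.exponential(1.0 / rate_per_ms)
    events.sort()
    return InputSpikeTrain.from_pairs(events)


def two_neuron_setup(seed: int, n_inputs: int = 100, rate_hz: float = 200.0,
                     t_end: float = 100.0, w_ab: float = 5.0,
                     input_mean: float = 0.014, input_std: float = 0.004):
    """Poisson-driven neuron A feeding neuron B across weight ``w_ab``.

    Input weights are drawn so A fires a handful of times over the
    horizon; ``w_ab`` makes B respond to A's spikes.  Returns
    ``(config, inputs, loss_head)`` with loss = sum of B's spike times.
    """
    rng = np.random.default_rng(seed)
    inputs = poisson_input_train(n_inputs, rate_hz, t_end, rng)
    w_in = np.zeros((2, n_inputs))
    w_in[0] = rng.normal(input_mean, input_std, n_inputs)
    w_rec = np.zeros((2, 2))
    w_rec[1, 0] = w_ab
    config = NetworkConfig(tau_mem=20.0, tau_syn=5.0, w_rec=w_rec,
                           w_in=w_in, t_end=t_end)
    return config, inputs, SpikeTimeWeightedLoss({1: 1.0})


@dataclass
class GradCheckResult:
    rows: list[tuple]
    max_rel_error: float
    n_spikes_a: int
    n_spikes_b: int


def gradient_check_experiment(seed: int = 0, n_input_weights: int = 20,
                              epsilon: float = 1e-6) -> GradCheckResult:
    """Adjoint vs central-difference gradients on the two-neuron
    benchmark: the A->B weight plus ``n_input_weights`` input weights.

    Entries where the finite-difference guard detects a spike-count
    change are flagged critical and excluded from the maximum relative
    error.
    """
    from .forward import simulate

    config, inputs, loss_head = two_neuron_setup(seed)
    record, _ = simulate(config, inputs)
    _, grads = eventprop_gradient(config, inputs, loss_head)

    rng = np.random.default_rng(seed + 1)
    chans = rng.choice(config.n_inputs, size=min(n_input_weights,
                                                 config.n_inputs),
                       replace=False)
    entries = [("rec", 1, 0)] + [("in", 0, int(c)) for c in chans]
    fd, critical = central_difference_gradient(
        config, inputs, loss_head, entries, FiniteDiffSpec(epsilon=epsilon))
    ep = np.array([grads.g_rec[1, 0]]
                  + [grads.g_in[0, int(c)] for c in chans])
    rel = np.abs(ep - fd) / np.maximum(np.abs(fd), 1e-300)
    rows = []
    for (kind, j, i), e, f, r, c in zip(entries, ep, fd, rel, critical):
        rows.append((f"{kind}[{j},{i}]", e, f, r, bool(c)))
    ok = ~critical
    max_rel = float(rel[ok].max()) if ok.any() else float("nan")
    return GradCheckResult(rows=rows, max_rel_error=max_rel,
                           n_spikes_a=len(record.spikes_of(0)),
                           n_spikes_b=len(record.spikes_of(1)))


def train_mnist_experiment(data_dir: str, seed: int = 0, epochs: int = 100,
                           n_hidden: int = 350, batch_size: int = 5,
                           out_dir: str | None = None,
                           n_train: int | None = None) -> dict:
    """Optional long-running MNIST experiment (voltage-maximum loss).

    Requires the IDX files locally; never downloads.  5000 training
    samples are split off as the validation set.  Returns summary
    metrics.
    """
    from .adjoint import GradientAccumulator
    from .data import EncodingConfig, drop_spikes, encode_mnist, load_mnist
    from .training import (InitSpec, OptimizerState, RunConfig, adam_step,
                           build_feedforward, evaluate, _make_head)

    run = RunConfig(n_hidden=n_hidden, n_out=10, epochs=epochs,
                    batch_size=batch_size, seed=seed, t_end=30.0,
                    loss="max_over_time",
                    encoding=EncodingConfig(t_max=20.0, p_drop=0.2),
                    init=InitSpec(hidden_mean=0.078, hidden_std=0.045,
                                  output_mean=0.2, output_std=0.37))
    images, labels = load_mnist(data_dir, "train")
    images_te, labels_te = load_mnist(data_dir, "test")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(images))
    val_idx, tr_idx = perm[:5000], perm[5000:]
    if n_train is not None:
        tr_idx = tr_idx[:n_train]

    enc = lambda im: encode_mnist(im, run.encoding)  # noqa: E731
    enc_val = [enc(images[i]) for i in val_idx]
    enc_te = [enc(im) for im in images_te]

    config = build_feedforward(run, n_in=784)
    opt = OptimizerState.zeros(config, eta=run.eta,
                               decay_factor=run.decay_factor)
    history = []
    from .adjoint import eventprop_gradient as _grad
    for epoch in range(epochs):
        order = rng.permutation(tr_idx)
        epoch_loss, n_batches = 0.0, 0
        for s in range(0, len(order), batch_size):
            batch = order[s:s + batch_size]
            acc = GradientAccumulator.zeros(config)
            for i in batch:
                spikes = drop_spikes(enc(images[i]), run.encoding.p_drop,
                                     int(rng.integers(2 ** 31)))
                head = _make_head(run, int(labels[i]), len(batch))
                loss, g = _grad(config, spikes, head)
                epoch_loss += loss
                acc.g_rec += g.g_rec
                acc.g_in += g.g_in
            config = adam_step(opt, config, acc)
            n_batches += 1
        opt.decay()
        _, val_acc, _ = evaluate(run, config, enc_val, labels[val_idx])
        history.append({"epoch": epoch,
                        "train_loss": epoch_loss / max(n_batches, 1),
                        "val_acc": val_acc})
    _, test_acc, confusion = evaluate(run, config, enc_te, labels_te)
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "confusion.csv", confusion, fmt="%d", delimiter=",")
    return {"test_acc": test_acc, "history": history}
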