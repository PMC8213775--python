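"""Minibatch training with Adam on latency-encoded spike datasets.

A two-layer network is expressed in the recurrent formalism as one
block-structured weight matrix: neurons ``0..H-1`` are the hidden layer
(driven by the input weights), neurons ``H..H+O-1`` the outputs, driven
by the hidden->output block of the recurrent matrix.  Gradients come
from the event-driven adjoint pass per sample; the 1/N_batch factor
lives in the loss heads, so summing per-sample gradients yields the
batch gradient exactly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .adjoint import GradientAccumulator, eventprop_gradient
from .data import EncodingConfig, encode_yinyang, generate_yinyang
from .forward import simulate
from .losses import (
    MaxVoltageLossConfig,
    MaxVoltageLossHead,
    TTFSLossConfig,
    TTFSLossHead,
)
from .network import InputSpikeTrain, NetworkConfig

log = logging.getLogger(__name__)

__all__ = [
    "InitSpec",
    "OptimizerState",
    "RunConfig",
    "init_weights",
    "build_feedforward",
    "adam_step",
    "train",
    "evaluate",
    "TrainResult",
]


@dataclass
class InitSpec:
    """Gaussian initialisation statistics per weight block (raw per-weight
    mean/std, no fan-in scaling)."""

    hidden_mean: float = 1.5
    hidden_std: float = 0.78
    output_mean: float = 0.93
    output_std: float = 0.1

    def __post_init__(self) -> None:
        if self.hidden_std < 0 or self.output_std < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class OptimizerState:
    """Adam moments for (w_rec, w_in) plus the step counter and the
    learning-rate schedule."""

    m_rec: np.ndarray
    v_rec: np.ndarray
    m_in: np.ndarray
    v_in: np.ndarray
    step: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    eta: float = 5e-3
    decay_factor: float = 0.95
    lr_scale: float = 1.0

    @classmethod
    def zeros(cls, config: NetworkConfig, **kwargs) -> "OptimizerState":
        return cls(m_rec=np.zeros_like(config.w_rec),
                   v_rec=np.zeros_like(config.w_rec),
                   m_in=np.zeros_like(config.w_in),
                   v_in=np.zeros_like(config.w_in), **kwargs)

    def decay(self) -> None:
        self.lr_scale *= self.decay_factor


@dataclass
class RunConfig:
    """One training run on the Yin-Yang task (defaults follow the
    reference hyperparameter set: 5 inputs, hidden layer, 3 outputs,
    first-spike-time loss)."""

    n_hidden: int = 200
    n_out: int = 3
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0
    n_train: int = 5000
    n_val: int = 1000
    n_test: int = 1000
    t_end: float = 45.0
    tau_mem: float = 20.0
    tau_syn: float = 5.0
    loss: str = "ttfs"
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    init: InitSpec = field(default_factory=InitSpec)
    eta: float = 5e-3
    decay_factor: float = 0.95
    out_dir: str | None = None


@dataclass
class TrainResult:
    config: NetworkConfig
    history: list[dict]
    best_epoch: int
    best_val_acc: float
    test_acc_best: float
    test_acc_final: float


def init_weights(spec: InitSpec, n_in: int, n_hidden: int, n_out: int,
                 seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw the block weight matrices: returns (w_rec, w_in) for the
    stacked hidden+output network.  Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    n = n_hidden + n_out
    w_in = np.zeros((n, n_in))
    w_in[:n_hidden] = rng.normal(spec.hidden_mean, spec.hidden_std,
                                 (n_hidden, n_in))
    w_rec = np.zeros((n, n))
    w_rec[n_hidden:, :n_hidden] = rng.normal(spec.output_mean,
                                             spec.output_std,
                                             (n_out, n_hidden))
    return w_rec, w_in


def build_feedforward(run: RunConfig, n_in: int = 5,
                      firing_outputs: bool | None = None) -> NetworkConfig:
    """Assemble the NetworkConfig for a two-layer run.

    Outputs fire for the first-spike-time loss and are non-firing leaky
    integrators for the max-voltage loss (overridable).
    """
    if firing_outputs is None:
        firing_outputs = run.loss == "ttfs"
    w_rec, w_in = init_weights(run.init, n_in, run.n_hidden, run.n_out,
                               run.seed)
    mask = np.ones(run.n_hidden + run.n_out, dtype=bool)
    if not firing_outputs:
        mask[run.n_hidden:] = False
    return NetworkConfig(tau_mem=run.tau_mem, tau_syn=run.tau_syn,
                         w_rec=w_rec, w_in=w_in, firing_mask=mask,
                         t_end=run.t_end)


def adam_step(opt: OptimizerState, config: NetworkConfig,
              grads: GradientAccumulator) -> NetworkConfig:
    """One bias-corrected Adam update at the current decayed rate."""
    if not (np.all(np.isfinite(grads.g_rec))
            and np.all(np.isfinite(grads.g_in))):
        raise FloatingPointError(
            "non-finite gradient encountered (max |g_rec|="
            f"{np.nanmax(np.abs(grads.g_rec)):.3e}); likely a critical "
            "point was crossed")
    opt.step += 1
    lr = opt.eta * opt.lr_scale
    c1 = 1.0 - opt.beta1 ** opt.step
    c2 = 1.0 - opt.beta2 ** opt.step
    new = {}
    for name, g, m, v, w in (
            ("w_rec", grads.g_rec, opt.m_rec, opt.v_rec, config.w_rec),
            ("w_in", grads.g_in, opt.m_in, opt.v_in, config.w_in)):
        m[...] = opt.beta1 * m + (1 - opt.beta1) * g
        v[...] = opt.beta2 * v + (1 - opt.beta2) * g * g
        update = lr * (m / c1) / (np.sqrt(v / c2) + opt.eps)
        new[name] = w - update
    new["w_rec"][np.diag_indices_from(new["w_rec"])] = 0.0
    return config.with_weights(w_rec=new["w_rec"], w_in=new["w_in"])


def _make_head(run: RunConfig, label: int, batch_size: int):
    out_neurons = tuple(range(run.n_hidden, run.n_hidden + run.n_out))
    if run.loss == "ttfs":
        return TTFSLossHead(TTFSLossConfig(output_neurons=out_neurons),
                            label, batch_size)
    if run.loss == "max_over_time":
        return MaxVoltageLossHead(
            MaxVoltageLossConfig(readout_neurons=out_neurons), label,
            batch_size)
    raise ValueError(f"unknown loss head {run.loss!r}")


def _predict(run: RunConfig, config: NetworkConfig,
             spikes: InputSpikeTrain) -> int:
    record, traj = simulate(config, spikes)
    head = _make_head(run, 0, 1)
    if run.loss == "ttfs":
        return head.predict(record)
    return head.predict(traj)


def evaluate(run: RunConfig, config: NetworkConfig, encoded: list,
             labels: np.ndarray):
    """Forward passes only: mean loss, accuracy and confusion matrix.

    Classification-rule ties are broken toward the lowest class index.
    """
    n_classes = run.n_out
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    total_loss = 0.0
    for spikes, label in zip(encoded, labels):
        record, traj = simulate(config, spikes)
        head = _make_head(run, int(label), 1)
        loss, _ = head.evaluate(record, traj, config)
        total_loss += loss
        pred = head.predict(record if run.loss == "ttfs" else traj)
        confusion[label, pred] += 1
    acc = np.trace(confusion) / max(len(labels), 1)
    return total_loss / max(len(labels), 1), acc, confusion


def _encode_dataset(xy: np.ndarray, cfg: EncodingConfig) -> list:
    return [encode_yinyang(x, y, cfg) for x, y in xy]


def train(run: RunConfig, progress: bool = False) -> TrainResult:
    """Train on the procedurally generated Yin-Yang task.

    Per epoch: seeded shuffle, per-minibatch adjoint gradients summed
    over samples, one Adam step per batch, learning rate decayed by the
    configured factor at epoch end.  Records train loss and validation /
    test accuracy per epoch; the best epoch is selected by validation
    accuracy and the test accuracy is reported both there and at the
    final epoch.
    """
    ss = np.random.SeedSequence(run.seed)
    seed_train, seed_val, seed_test, seed_shuffle = (
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4))

    xy_tr, y_tr = generate_yinyang(run.n_train, seed_train)
    xy_va, y_va = generate_yinyang(run.n_val, seed_val)
    xy_te, y_te = generate_yinyang(run.n_test, seed_test)
    enc_tr = _encode_dataset(xy_tr, run.encoding)
    enc_va = _encode_dataset(xy_va, run.encoding)
    enc_te = _encode_dataset(xy_te, run.encoding)

    config = build_feedforward(run)
    opt = OptimizerState.zeros(config, eta=run.eta,
                               decay_factor=run.decay_factor)
    rng = np.random.default_rng(seed_shuffle)

    history: list[dict] = []
    best = (-1.0, 0, None)  # (val_acc, epoch, weights)
    for epoch in range(run.epochs):
        order = rng.permutation(run.n_train)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, run.n_train, run.batch_size):
            batch = order[start:start + run.batch_size]
            acc_grad = GradientAccumulator.zeros(config)
            batch_loss = 0.0
            for idx in batch:
                head = _make_head(run, int(y_tr[idx]), len(batch))
                loss, g = eventprop_gradient(config, enc_tr[idx], head)
                batch_loss += loss
                acc_grad.g_rec += g.g_rec
                acc_grad.g_in += g.g_in
            config = adam_step(opt, config, acc_grad)
            epoch_loss += batch_loss
            n_batches += 1
        opt.decay()

        _, val_acc, _ = evaluate(run, config, enc_va, y_va)
        _, test_acc, _ = evaluate(run, config, enc_te, y_te)
        history.append({"epoch": epoch, "train_loss": epoch_loss / n_batches,
                        "val_acc": val_acc, "test_acc": test_acc})
        if val_acc > best[0]:
            best = (val_acc, epoch, (config.w_rec.copy(),
                                     config.w_in.copy()))
        if progress:
            log.info("epoch %d: loss %.4f val %.3f test %.3f", epoch,
                     epoch_loss / n_batches, val_acc, test_acc)

    best_val, best_epoch, best_w = best
    test_final = history[-1]["test_acc"] if history else float("nan")
    if best_w is not None:
        best_cfg = config.with_weights(w_rec=best_w[0], w_in=best_w[1])
        _, test_best, _ = evaluate(run, best_cfg, enc_te, y_te)
    else:
        test_best = test_final

    if run.out_dir:
        out = Path(run.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "metrics.csv", "w", newline="") as f:
            writer = csv.DictWriter(
                f, fieldnames=["epoch", "train_loss", "val_acc", "test_acc"])
            writer.writeheader()
            writer.writerows(history)

    return TrainResult(config=config, history=history, best_epoch=best_epoch,
                       best_val_acc=best_val, test_acc_best=test_best,
                       test_acc_final=test_final)
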