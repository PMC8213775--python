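"""Scikit-learn style estimator over the spiking training engine.

``EventPropClassifier`` wraps the event-driven training loop behind the
familiar fit/predict surface, so the spiking network composes with
sklearn model selection and pipelines.  ``X`` holds 2-D points in
[0, 1]^2 which are latency-encoded as (x, 1-x, y, 1-y) spikes plus a
bias spike; ``y`` holds integer class labels.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data import EncodingConfig, encode_yinyang
from .forward import simulate
from .training import InitSpec, RunConfig, _make_head

__all__ = ["EventPropClassifier"]


class EventPropClassifier(BaseEstimator, ClassifierMixin):
    """Two-layer spiking classifier trained with exact event-based
    gradients.

    Parameters mirror the training run configuration: hidden layer
    width, loss head (``"ttfs"`` classifies by the earliest output
    spike; ``"max_over_time"`` by the largest readout voltage
    deflection), epoch count, Adam learning rate with per-epoch decay,
    latency-encoding window and the Gaussian weight initialisation
    statistics.

    Attributes (after ``fit``)
    --------------------------
    network_ : NetworkConfig
        Trained weights and neuron parameters.
    history_ : list of dict
        Per-epoch train loss and validation/test accuracy of the
        internal split.
    classes_ : ndarray
        Sorted class labels.
    """

    def __init__(self, n_hidden: int = 200, loss: str = "ttfs",
                 epochs: int = 40, batch_size: int = 32, eta: float = 5e-3,
                 decay_factor: float = 0.95, t_max: float = 30.0,
                 t_end: float = 45.0, tau_mem: float = 20.0,
                 tau_syn: float = 5.0, init: InitSpec | None = None,
                 val_fraction: float = 0.15, random_state: int = 0):
        self.n_hidden = n_hidden
        self.loss = loss
        self.epochs = epochs
        self.batch_size = batch_size
        self.eta = eta
        self.decay_factor = decay_factor
        self.t_max = t_max
        self.t_end = t_end
        self.tau_mem = tau_mem
        self.tau_syn = tau_syn
        self.init = init
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _run_config(self, n_out: int) -> RunConfig:
        return RunConfig(
            n_hidden=self.n_hidden, n_out=n_out, epochs=self.epochs,
            batch_size=self.batch_size, seed=self.random_state,
            t_end=self.t_end, tau_mem=self.tau_mem, tau_syn=self.tau_syn,
            loss=self.loss, encoding=EncodingConfig(t_max=self.t_max),
            init=self.init or InitSpec(), eta=self.eta,
            decay_factor=self.decay_factor)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2) points in [0, 1]^2")
        self.classes_ = np.unique(y)
        run = self._run_config(n_out=len(self.classes_))
        label_index = {c: k for k, c in enumerate(self.classes_)}
        labels = np.array([label_index[c] for c in y])

        # train on the supplied data instead of the generated dataset
        from .adjoint import GradientAccumulator, eventprop_gradient
        from .training import OptimizerState, adam_step, build_feedforward

        rng = np.random.default_rng(self.random_state)
        enc = [encode_yinyang(a, b, run.encoding) for a, b in X]
        n_val = max(1, int(len(X) * self.val_fraction))
        perm = rng.permutation(len(X))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

        config = build_feedforward(run)
        opt = OptimizerState.zeros(config, eta=run.eta,
                                   decay_factor=run.decay_factor)
        history = []
        best = (-1.0, None)
        for epoch in range(run.epochs):
            order = rng.permutation(tr_idx)
            epoch_loss, n_batches = 0.0, 0
            for s in range(0, len(order), run.batch_size):
                batch = order[s:s + run.batch_size]
                acc = GradientAccumulator.zeros(config)
                for i in batch:
                    head = _make_head(run, int(labels[i]), len(batch))
                    loss, g = eventprop_gradient(config, enc[i], head)
                    epoch_loss += loss
                    acc.g_rec += g.g_rec
                    acc.g_in += g.g_in
                config = adam_step(opt, config, acc)
                n_batches += 1
            opt.decay()
            val_acc = self._accuracy(run, config,
                                     [enc[i] for i in val_idx],
                                     labels[val_idx])
            history.append({"epoch": epoch,
                            "train_loss": epoch_loss / max(n_batches, 1),
                            "val_acc": val_acc})
            if val_acc > best[0]:
                best = (val_acc, (config.w_rec.copy(), config.w_in.copy()))
        if best[1] is not None:
            config = config.with_weights(*best[1])
        self.network_ = config
        self.run_ = run
        self.history_ = history
        return self

    def _accuracy(self, run, config, encoded, labels) -> float:
        preds = [self._predict_one(run, config, e) for e in encoded]
        return float(np.mean(np.asarray(preds) == labels)) if labels.size \
            else 0.0

    @staticmethod
    def _predict_one(run, config, spikes) -> int:
        record, traj = simulate(config, spikes)
        head = _make_head(run, 0, 1)
        return head.predict(record if run.loss == "ttfs" else traj)

    def predict(self, X):
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=float)
        enc = [encode_yinyang(a, b, self.run_.encoding) for a, b in X]
        idx = [self._predict_one(self.run_, self.network_, e) for e in enc]
        return self.classes_[np.asarray(idx)]
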