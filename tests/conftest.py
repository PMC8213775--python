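"""Shared fixtures: small random networks with guaranteed activity and
a cached tiny training run."""

from __future__ import annotations

import numpy as np
import pytest

from eventprop import (
    EncodingConfig,
    InputSpikeTrain,
    NetworkConfig,
    RunConfig,
    simulate,
    train,
)


def make_random_net(seed: int, n_firing: int = 3, n_readout: int = 0,
                    n_inputs: int = 2, t_end: float = 40.0,
                    recurrent: bool = True):
    """Random small network with enough drive that the firing neurons
    actually spike; readout neurons (if any) are non-firing."""
    rng = np.random.default_rng(seed)
    n = n_firing + n_readout
    w_in = np.zeros((n, n_inputs))
    w_in[:n_firing] = rng.normal(2.0, 0.6, (n_firing, n_inputs))
    w_rec = np.zeros((n, n))
    if recurrent:
        w_rec[:n_firing, :n_firing] = rng.normal(0.5, 0.4,
                                                 (n_firing, n_firing))
    if n_readout:
        w_rec[n_firing:, :n_firing] = rng.normal(1.0, 0.4,
                                                 (n_readout, n_firing))
    np.fill_diagonal(w_rec, 0.0)
    mask = np.ones(n, dtype=bool)
    mask[n_firing:] = False
    config = NetworkConfig(tau_mem=20.0, tau_syn=5.0, w_rec=w_rec,
                           w_in=w_in, firing_mask=mask, t_end=t_end)
    times = np.sort(rng.uniform(0.0, 0.5 * t_end, 4))
    channels = rng.integers(0, n_inputs, 4)
    return config, InputSpikeTrain(times, channels)


def spiking_random_net(seed: int, **kwargs):
    """Like make_random_net but retries seeds until at least one spike
    occurs (gradient tests need activity)."""
    for trial in range(20):
        config, inputs = make_random_net(seed + 1000 * trial, **kwargs)
        record, _ = simulate(config, inputs)
        if len(record) >= 2:
            return config, inputs
    raise RuntimeError("could not find an active random network")


@pytest.fixture(scope="session")
def tiny_train_result():
    """One small Yin-Yang training run shared by several tests."""
    run = RunConfig(n_hidden=30, epochs=4, n_train=150, n_val=60, n_test=60,
                    seed=7, encoding=EncodingConfig(t_max=30.0))
    return run, train(run)
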