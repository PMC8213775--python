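"""Serialisation of spike data and network configurations.

Spike trains and spike records round-trip through CSV (columns
``time_ms, index`` plus the cached backward-pass quantities for records)
and through HDF5 groups; network configurations split into a YAML file
for scalars and an HDF5 file for the weight matrices.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np
import yaml

from .network import InputSpikeTrain, NetworkConfig, SpikeEvent, SpikeRecord

__all__ = [
    "spike_train_to_csv", "spike_train_from_csv",
    "spike_record_to_csv", "spike_record_from_csv",
    "spikes_to_hdf5", "spikes_from_hdf5",
    "config_to_files", "config_from_files",
]


def spike_train_to_csv(train: InputSpikeTrain, path: str | Path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["time_ms", "index"])
        for t, c in zip(train.times, train.channels):
            w.writerow([repr(float(t)), int(c)])


def spike_train_from_csv(path: str | Path) -> InputSpikeTrain:
    times, channels = [], []
    with open(path, newline="") as f:
        for row in csv.DictReader(f):
            times.append(float(row["time_ms"]))
            channels.append(int(row["index"]))
    return InputSpikeTrain(np.array(times), np.array(channels, dtype=int))


def spike_record_to_csv(record: SpikeRecord, path: str | Path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["time_ms", "index", "i_minus", "vdot_minus"])
        for ev in record.events:
            w.writerow([repr(float(ev.time)), int(ev.neuron),
                        repr(float(ev.i_minus)),
                        repr(float(ev.vdot_minus))])


def spike_record_from_csv(path: str | Path) -> SpikeRecord:
    record = SpikeRecord()
    with open(path, newline="") as f:
        for row in csv.DictReader(f):
            record.events.append(SpikeEvent(
                time=float(row["time_ms"]), neuron=int(row["index"]),
                i_minus=float(row["i_minus"]),
                vdot_minus=float(row["vdot_minus"])))
    return record


def spikes_to_hdf5(obj: InputSpikeTrain | SpikeRecord, group: h5py.Group) -> None:
    """Write a spike train or record into an HDF5 group (datasets
    ``times``/``indices``, plus caches for records)."""
    if isinstance(obj, SpikeRecord):
        group.create_dataset("times", data=obj.times)
        group.create_dataset("indices", data=obj.neurons)
        group.create_dataset(
            "i_minus", data=np.array([e.i_minus for e in obj.events]))
        group.create_dataset(
            "vdot_minus", data=np.array([e.vdot_minus for e in obj.events]))
    else:
        group.create_dataset("times", data=obj.times)
        group.create_dataset("indices", data=obj.channels)


def spikes_from_hdf5(group: h5py.Group) -> InputSpikeTrain | SpikeRecord:
    times = np.asarray(group["times"])
    indices = np.asarray(group["indices"], dtype=int)
    if "i_minus" in group:
        record = SpikeRecord()
        i_minus = np.asarray(group["i_minus"])
        vdot = np.asarray(group["vdot_minus"])
        for t, n, im, vd in zip(times, indices, i_minus, vdot):
            record.events.append(SpikeEvent(float(t), int(n), float(im),
                                            float(vd)))
        return record
    return InputSpikeTrain(times, indices)


def config_to_files(config: NetworkConfig, yaml_path: str | Path,
                    h5_path: str | Path) -> None:
    scalars = {
        "tau_mem": float(config.tau_mem),
        "tau_syn": float(config.tau_syn),
        "threshold": float(config.threshold),
        "t_end": float(config.t_end),
        "spike_cap": int(config.spike_cap),
        "eps_crit": float(config.eps_crit),
        "weights_file": str(h5_path),
    }
    with open(yaml_path, "w") as f:
        yaml.safe_dump(scalars, f)
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("w_rec", data=config.w_rec)
        f.create_dataset("w_in", data=config.w_in)
        f.create_dataset("firing_mask", data=config.firing_mask)


def config_from_files(yaml_path: str | Path,
                      h5_path: str | Path | None = None) -> NetworkConfig:
    with open(yaml_path) as f:
        scalars = yaml.safe_load(f)
    h5_path = h5_path or scalars["weights_file"]
    with h5py.File(h5_path, "r") as f:
        w_rec = np.asarray(f["w_rec"])
        w_in = np.asarray(f["w_in"])
        mask = np.asarray(f["firing_mask"], dtype=bool)
    scalars.pop("weights_file", None)
    return NetworkConfig(w_rec=w_rec, w_in=w_in, firing_mask=mask, **scalars)
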