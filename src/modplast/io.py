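"""Serialization: spike trains, weight trajectories, run summaries, configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .inputs import InputEnsembleConfig, SpikeTrainSet
from .plasticity import WeightTrajectory

__all__ = [
    "write_spikes_text",
    "read_spikes_text",
    "write_spikes_hdf5",
    "read_spikes_hdf5",
    "trajectory_to_frame",
    "write_trajectory_csv",
    "write_trajectory_hdf5",
    "write_summary_json",
    "load_input_config",
]


def write_spikes_text(trains: SpikeTrainSet, path: str | Path) -> None:
    """Two-column text format: neuron_id (1-based) and spike time in seconds."""
    with open(path, "w") as fh:
        fh.write("# neuron_id\tspike_time_s\n")
        for i, times in enumerate(trains.spikes, start=1):
            for t in times:
                fh.write(f"{i}\t{t:.6f}\n")


def read_spikes_text(path: str | Path) -> dict[int, np.ndarray]:
    """Read the two-column text format back as {neuron_id: spike times}."""
    arr = np.loadtxt(path, ndmin=2)
    out: dict[int, np.ndarray] = {}
    if arr.size == 0:
        return out
    for nid in np.unique(arr[:, 0]).astype(int):
        out[nid] = np.sort(arr[arr[:, 0] == nid, 1])
    return out


def write_spikes_hdf5(trains: SpikeTrainSet, path: str | Path) -> None:
    """HDF5 layout: /spikes/neuron_<i> datasets, /rates matrix, /meta attrs."""
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        for i, times in enumerate(trains.spikes, start=1):
            g.create_dataset(f"neuron_{i}", data=np.asarray(times))
        f.create_dataset("rates", data=trains.rate_traces)
        meta = f.create_group("meta")
        meta.attrs["duration"] = trains.duration
        meta.attrs["dt"] = trains.dt
        meta.attrs["signal_dt"] = trains.signal_dt
        meta.attrs["n_inputs"] = trains.n_inputs


def read_spikes_hdf5(path: str | Path) -> SpikeTrainSet:
    with h5py.File(path, "r") as f:
        n = int(f["meta"].attrs["n_inputs"])
        dt = float(f["meta"].attrs["dt"])
        spikes = [np.asarray(f[f"spikes/neuron_{i}"]) for i in range(1, n + 1)]
        return SpikeTrainSet(
            duration=float(f["meta"].attrs["duration"]),
            dt=dt,
            spikes=spikes,
            bins=[np.round(s / dt).astype(np.int64) for s in spikes],
            rate_traces=np.asarray(f["rates"]),
            signal_dt=float(f["meta"].attrs["signal_dt"]),
        )


def trajectory_to_frame(traj: WeightTrajectory) -> pd.DataFrame:
    """Wide CSV layout: time_s, w_1 .. w_N."""
    n = traj.weights.shape[1]
    df = pd.DataFrame(traj.weights, columns=[f"w_{i}" for i in range(1, n + 1)])
    df.insert(0, "time_s", traj.times)
    return df


def write_trajectory_csv(traj: WeightTrajectory, path: str | Path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False)


def write_trajectory_hdf5(traj: WeightTrajectory, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("weights", data=traj.weights)
        f.attrs["w_min"] = traj.w_min
        f.attrs["w_max"] = traj.w_max


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_summary_json(summary: dict, path: str | Path) -> None:
    """Write a metrics/parameters summary as JSON (numpy types coerced)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2)


def load_input_config(path: str | Path) -> InputEnsembleConfig:
    """Load an input-ensemble config block from a YAML (or JSON) file.

    Keys mirror :class:`InputEnsembleConfig` fields; unknown keys raise.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "training_neighbor_profile" in data and data["training_neighbor_profile"] is not None:
        data["training_neighbor_profile"] = tuple(data["training_neighbor_profile"])
    valid = {f.name for f in dataclasses.fields(InputEnsembleConfig)}
    unknown = set(data) - valid
    if unknown:
        raise KeyError(f"unknown input config keys: {sorted(unknown)}")
    return InputEnsembleConfig(**data)
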