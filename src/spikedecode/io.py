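"""Readers and writers for spike/output data (HDF5 and delimited text).

HDF5 layout
-----------
``spikes/neuron_000 .. neuron_{N-1}``  per-neuron spike-time vectors (s), or
``counts``                             pre-binned spike-count matrix;
``outputs``                            output-sample matrix (n_samples x d);
``output_times``                       sample times (s);
root attributes ``duration`` and, for binned files, ``bin_size`` plus the
lag-window attributes ``bins_before`` / ``bins_current`` / ``bins_after``.

CSV layout
----------
Spike events: columns ``neuron_id,time_s``.  Outputs: columns
``time_s,out1..outd``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from spikedecode.data_format import BinnedDataset, LagSpec, SpikeData
from spikedecode.synthetic import SyntheticGroundTruth

__all__ = [
    "read_spikes_csv",
    "read_outputs_csv",
    "read_spikes_hdf5",
    "read_outputs_hdf5",
    "write_dataset_hdf5",
    "read_binned_hdf5",
    "write_binned_hdf5",
]


def read_spikes_csv(path: str | Path, duration: float | None = None,
                    n_neurons: int | None = None) -> SpikeData:
    """Read a spike-events file with columns ``neuron_id,time_s``."""
    df = pd.read_csv(path)
    if not {"neuron_id", "time_s"}.issubset(df.columns):
        raise ValueError("spike CSV needs columns neuron_id,time_s")
    n = n_neurons or int(df["neuron_id"].max()) + 1
    if duration is None:
        duration = float(df["time_s"].max()) + 1e-9
    spike_times = [
        np.sort(df.loc[df["neuron_id"] == i, "time_s"].to_numpy(dtype=float))
        for i in range(n)
    ]
    return SpikeData(spike_times=spike_times, duration=duration)


def read_outputs_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an outputs file ``time_s,out1..outd`` -> (times, values)."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ValueError("outputs CSV needs columns time_s,out1..outd")
    times = df["time_s"].to_numpy(dtype=float)
    values = df.drop(columns="time_s").to_numpy(dtype=float)
    return times, values


def read_spikes_hdf5(path: str | Path) -> SpikeData:
    with h5py.File(path, "r") as f:
        if "spikes" not in f:
            raise ValueError("HDF5 file has no 'spikes' group")
        names = sorted(f["spikes"])
        spike_times = [f["spikes"][name][()] for name in names]
        duration = float(f.attrs["duration"])
    return SpikeData(spike_times=spike_times, duration=duration)


def read_outputs_hdf5(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        return f["output_times"][()], np.atleast_2d(f["outputs"][()])


def write_dataset_hdf5(
    path: str | Path,
    spikes: SpikeData,
    output_times: np.ndarray,
    output_values: np.ndarray,
    truth: SyntheticGroundTruth | None = None,
) -> None:
    """Write raw spike times + output samples (+ optional ground truth)."""
    with h5py.File(path, "w") as f:
        f.attrs["duration"] = spikes.duration
        g = f.create_group("spikes")
        width = len(str(spikes.n_neurons - 1))
        for i, st in enumerate(spikes.spike_times):
            g.create_dataset(f"neuron_{i:0{width}d}", data=st)
        f.create_dataset("output_times", data=np.asarray(output_times))
        f.create_dataset("outputs", data=np.asarray(output_values))
        if truth is not None:
            tg = f.create_group("ground_truth")
            tg.attrs["mode"] = truth.mode
            tg.attrs["seed"] = truth.seed
            tg.attrs["bin_size"] = truth.bin_size
            tg.create_dataset("rates", data=truth.rates)
            for group_name, d in (("kinematics", truth.kinematics),
                                  ("tuning_params", truth.tuning_params)):
                sub = tg.create_group(group_name)
                for k, v in d.items():
                    sub.create_dataset(k, data=np.asarray(v))


def read_ground_truth_hdf5(path: str | Path) -> SyntheticGroundTruth:
    with h5py.File(path, "r") as f:
        tg = f["ground_truth"]
        return SyntheticGroundTruth(
            mode=str(tg.attrs["mode"]),
            seed=int(tg.attrs["seed"]),
            bin_size=float(tg.attrs["bin_size"]),
            rates=tg["rates"][()],
            kinematics={k: v[()] for k, v in tg["kinematics"].items()},
            tuning_params={k: v[()] for k, v in tg["tuning_params"].items()},
        )


def write_binned_hdf5(path: str | Path, data: BinnedDataset,
                      lags: LagSpec | None = None) -> None:
    """Write a binned dataset with bin-size (and lag) metadata attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=data.counts)
        f.create_dataset("outputs", data=data.outputs)
        f.attrs["bin_size"] = data.bin_size
        if lags is not None:
            f.attrs["bins_before"] = lags.bins_before
            f.attrs["bins_current"] = lags.bins_current
            f.attrs["bins_after"] = lags.bins_after


def read_binned_hdf5(path: str | Path) -> tuple[BinnedDataset, LagSpec | None]:
    with h5py.File(path, "r") as f:
        data = BinnedDataset(
            counts=f["counts"][()],
            outputs=f["outputs"][()],
            bin_size=float(f.attrs["bin_size"]),
        )
        lags = None
        if "bins_before" in f.attrs:
            lags = LagSpec(
                bins_before=int(f.attrs["bins_before"]),
                bins_current=int(f.attrs["bins_current"]),
                bins_after=int(f.attrs["bins_after"]),
            )
    return data, lags
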