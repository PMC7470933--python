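"""Binning spike trains and continuous outputs onto a common time grid.

Decoding a continuous variable (hand velocity, animal position, ...) from a
population of spiking neurons starts from a shared discretization: spikes are
counted in bins of length ``R`` seconds, the output is averaged over the same
bins, and each output bin is predicted from the spike counts of all ``N``
neurons in a window of ``B`` surrounding bins.  Two layouts of that window are
needed downstream:

* a flat design matrix of shape ``K x (N*B)`` for regression-style decoders,
* a sequence tensor of shape ``K x N x B`` for recurrent decoders,

where ``K = n_bins - bins_before - bins_after`` is the number of output bins
whose full lag window lies inside the recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeData",
    "BinnedDataset",
    "LagSpec",
    "DesignMatrix",
    "SequenceTensor",
    "Scaler",
    "bin_spikes",
    "bin_output",
    "make_design_matrix",
    "make_sequence_tensor",
    "fit_scaler",
    "apply_scaler",
]


@dataclass
class SpikeData:
    """Spike event times for a population of neurons.

    Parameters
    ----------
    spike_times
        One ascending array of event times (seconds) per neuron.  A neuron
        with no spikes is an empty array.
    duration
        Recording length ``T`` in seconds.  All spike times must lie in
        ``[0, T)``.
    """

    spike_times: list[np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if len(self.spike_times) < 1:
            raise ValueError("need at least one neuron")
        self.spike_times = [np.asarray(st, dtype=float) for st in self.spike_times]
        for i, st in enumerate(self.spike_times):
            if st.size and (np.any(np.diff(st) < 0)):
                raise ValueError(f"spike times of neuron {i} are not sorted ascending")
            if st.size and (st[0] < 0 or st[-1] >= self.duration):
                raise ValueError(
                    f"spike times of neuron {i} outside [0, duration)"
                )

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    @property
    def total_spikes(self) -> int:
        return int(sum(st.size for st in self.spike_times))


@dataclass
class BinnedDataset:
    """Aligned spike-count and output matrices on a common time grid.

    ``counts`` holds non-negative integer spike counts (rows = time bins,
    columns = neurons); ``outputs`` holds the per-bin mean of the continuous
    output (rows = the same time bins, columns = output dimensions).  Counts,
    not rates, are stored so that spike conservation can be checked exactly;
    a rate is ``count / bin_size`` where a decoder needs one.
    """

    counts: np.ndarray
    outputs: np.ndarray
    bin_size: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.outputs = np.atleast_2d(np.asarray(self.outputs, dtype=float))
        if self.outputs.shape[0] == 1 and self.counts.shape[0] != 1:
            self.outputs = self.outputs.T
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.counts.shape[0] != self.outputs.shape[0]:
            raise ValueError("counts and outputs must have equal row counts")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.outputs.shape[1]


@dataclass(frozen=True)
class LagSpec:
    """Lag window: which neural bins predict a given output bin.

    ``bins_before`` bins preceding the output bin, optionally the concurrent
    bin (``bins_current`` is 0 or 1), and ``bins_after`` bins following it.
    The window length is ``B = bins_before + bins_current + bins_after``.
    """

    bins_before: int = 0
    bins_current: int = 1
    bins_after: int = 0

    def __post_init__(self) -> None:
        if self.bins_before < 0 or self.bins_after < 0:
            raise ValueError("bins_before and bins_after must be non-negative")
        if self.bins_current not in (0, 1):
            raise ValueError("bins_current must be 0 or 1")
        if self.n_lags < 1:
            raise ValueError("lag window must contain at least one bin (B >= 1)")

    @property
    def n_lags(self) -> int:
        """B, the number of bins in the window."""
        return self.bins_before + self.bins_current + self.bins_after

    @property
    def offsets(self) -> np.ndarray:
        """Signed bin offsets of the window relative to the output bin."""
        off = list(range(-self.bins_before, 0))
        if self.bins_current:
            off.append(0)
        off.extend(range(1, self.bins_after + 1))
        return np.asarray(off, dtype=int)


@dataclass
class DesignMatrix:
    """Flat lagged covariates: ``X`` is ``K x (N*B)``, ``Y`` is ``K x d``.

    Column order is lag-major, neuron-minor: the first ``N`` columns are all
    neurons at the earliest lag, the next ``N`` at the following lag, and so
    on.  ``row_to_bin[k]`` is the index of the output bin predicted by row k.
    """

    X: np.ndarray
    Y: np.ndarray
    row_to_bin: np.ndarray
    lags: LagSpec
    n_neurons: int


@dataclass
class SequenceTensor:
    """Sequence layout for recurrent decoders: ``X3`` is ``K x N x B``.

    ``X3[k, :, j]`` holds the counts of all neurons at bin
    ``row_to_bin[k] + offsets[j]``; flattening lag-major reproduces the
    corresponding :class:`DesignMatrix` exactly.
    """

    X3: np.ndarray
    Y: np.ndarray
    row_to_bin: np.ndarray
    lags: LagSpec

    def flatten(self) -> np.ndarray:
        """Flatten to the ``K x (N*B)`` design-matrix layout."""
        K, N, B = self.X3.shape
        return self.X3.transpose(0, 2, 1).reshape(K, N * B)


def bin_spikes(spikes: SpikeData, bin_size: float) -> np.ndarray:
    """Count spikes of each neuron in half-open bins ``[t*R, (t+1)*R)``.

    The number of bins is ``floor(T / R)``; spikes falling in the trailing
    partial bin (if any) are dropped.  Returns an integer matrix of shape
    ``(n_bins, n_neurons)``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if spikes.duration < bin_size:
        raise ValueError("recording shorter than one bin")
    n_bins = int(np.floor(spikes.duration / bin_size + 1e-9))
    counts = np.zeros((n_bins, spikes.n_neurons), dtype=np.int64)
    for i, st in enumerate(spikes.spike_times):
        # floor puts a spike exactly on a boundary into the later bin;
        # indices >= n_bins belong to the dropped trailing remainder
        idx = np.floor(st / bin_size).astype(int)
        idx = idx[idx < n_bins]
        counts[:, i] = np.bincount(idx, minlength=n_bins)
    return counts


def bin_output(
    sample_times: np.ndarray,
    sample_values: np.ndarray,
    bin_size: float,
    n_bins: int,
) -> np.ndarray:
    """Average time-stamped output samples over the spike-count bin grid.

    Each bin value is the mean of the samples with ``t`` in
    ``[bin*R, (bin+1)*R)``.  Bins containing no sample are filled by linear
    interpolation between neighboring filled bins; leading and trailing gaps
    hold the nearest filled value.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    t = np.asarray(sample_times, dtype=float)
    v = np.atleast_2d(np.asarray(sample_values, dtype=float))
    if v.shape[0] == 1 and t.size != 1:
        v = v.T
    if t.size == 0:
        raise ValueError("empty output sample list")
    if v.shape[0] != t.size:
        raise ValueError("sample_times and sample_values length mismatch")

    idx = np.floor(t / bin_size + 1e-12).astype(int)
    keep = (idx >= 0) & (idx < n_bins)
    idx, v = idx[keep], v[keep]
    d = v.shape[1]
    out = np.full((n_bins, d), np.nan)
    occupancy = np.bincount(idx, minlength=n_bins).astype(float)
    filled = occupancy > 0
    if not filled.any():
        raise ValueError("no output samples fall inside the bin grid")
    for j in range(d):
        sums = np.bincount(idx, weights=v[:, j], minlength=n_bins)
        out[filled, j] = sums[filled] / occupancy[filled]
        if not filled.all():
            bins = np.arange(n_bins)
            out[~filled, j] = np.interp(bins[~filled], bins[filled], out[filled, j])
    return out


def _check_window(lags: LagSpec, n_bins: int) -> None:
    if n_bins <= lags.bins_before + lags.bins_after:
        raise ValueError(
            f"lag window ({lags.bins_before} before + {lags.bins_after} after) "
            f"leaves no predictable bins in a {n_bins}-bin recording"
        )


def make_sequence_tensor(data: BinnedDataset, lags: LagSpec) -> SequenceTensor:
    """Build the ``K x N x B`` tensor of lagged spike counts.

    The first ``bins_before`` and last ``bins_after`` output bins are
    excluded because their windows extend outside the recording, leaving
    ``K = n_bins - bins_before - bins_after`` predictable rows.
    """
    _check_window(lags, data.n_bins)
    K = data.n_bins - lags.bins_before - lags.bins_after
    row_to_bin = np.arange(K) + lags.bins_before
    offsets = lags.offsets
    # gather: X3[k, :, j] = counts[row_to_bin[k] + offsets[j], :]
    idx = row_to_bin[:, None] + offsets[None, :]        # K x B
    X3 = data.counts[idx, :].transpose(0, 2, 1).astype(float)
    Y = data.outputs[row_to_bin, :]
    return SequenceTensor(X3=X3, Y=Y, row_to_bin=row_to_bin, lags=lags)


def make_design_matrix(data: BinnedDataset, lags: LagSpec) -> DesignMatrix:
    """Build the flat ``K x (N*B)`` lagged design matrix (see module docs)."""
    seq = make_sequence_tensor(data, lags)
    return DesignMatrix(
        X=seq.flatten(),
        Y=seq.Y,
        row_to_bin=seq.row_to_bin,
        lags=lags,
        n_neurons=data.n_neurons,
    )


@dataclass
class Scaler:
    """Column-wise location/scale transform learned from training rows only.

    ``zscore`` subtracts the training mean and divides by the training SD;
    ``center`` only subtracts the mean; ``none`` is the identity.  The stored
    parameters are reused verbatim on validation/test rows, which is what
    keeps preprocessing leakage-free.
    """

    mode: str
    mean_: np.ndarray = field(default=None, repr=False)
    scale_: np.ndarray = field(default=None, repr=False)

    def transform(self, rows: np.ndarray) -> np.ndarray:
        rows = np.asarray(rows, dtype=float)
        if self.mode == "none":
            return rows.copy()
        return (rows - self.mean_) / self.scale_

    def inverse_transform(self, rows: np.ndarray) -> np.ndarray:
        rows = np.asarray(rows, dtype=float)
        if self.mode == "none":
            return rows.copy()
        return rows * self.scale_ + self.mean_


def fit_scaler(rows: np.ndarray, mode: str = "zscore") -> Scaler:
    """Learn per-column location and scale from (training) rows.

    In ``zscore`` mode a zero-variance column gets its scale clamped to 1
    (with a warning) so the transform stays finite.
    """
    if mode not in ("zscore", "center", "none"):
        raise ValueError(f"unknown scaler mode {mode!r}")
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    mean = rows.mean(axis=0)
    if mode == "zscore":
        scale = rows.std(axis=0)
        zero = scale == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance column(s); scale clamped to 1",
                stacklevel=2,
            )
            scale = np.where(zero, 1.0, scale)
    else:
        scale = np.ones_like(mean)
    return Scaler(mode=mode, mean_=mean, scale_=scale)


def apply_scaler(scaler: Scaler, rows: np.ndarray) -> np.ndarray:
    """Apply a fitted scaler; parameters are never re-estimated here."""
    return scaler.transform(rows)
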