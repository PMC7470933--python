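"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from spikedecode.data_format import BinnedDataset, LagSpec, bin_output, bin_spikes
from spikedecode.synthetic import simulate_cortical


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cortical_small():
    """~3 min of cosine-tuned cortical-like data, binned at 50 ms."""
    spikes, times, values, truth = simulate_cortical(
        n_neurons=20, duration=180.0, bin_size=0.05, seed=7,
    )
    counts = bin_spikes(spikes, 0.05)
    outputs = bin_output(times, values, 0.05, counts.shape[0])
    data = BinnedDataset(counts=counts, outputs=outputs, bin_size=0.05)
    return data, truth


@pytest.fixture(scope="session")
def cortical_design(cortical_small):
    """Train/test split of the small cortical dataset, z-scored features."""
    from spikedecode.data_format import apply_scaler, fit_scaler, make_design_matrix

    data, _ = cortical_small
    dm = make_design_matrix(data, LagSpec(bins_before=3, bins_current=1))
    K = dm.X.shape[0]
    train = np.arange(int(0.8 * K))
    test = np.arange(int(0.8 * K), K)
    xs = fit_scaler(dm.X[train], "zscore")
    ys = fit_scaler(dm.Y[train], "center")
    return {
        "Xtr": apply_scaler(xs, dm.X[train]),
        "Xte": apply_scaler(xs, dm.X[test]),
        "Ytr": apply_scaler(ys, dm.Y[train]),
        "Yte": apply_scaler(ys, dm.Y[test]),
        "dm": dm,
        "train": train,
        "test": test,
    }


@pytest.fixture
def linear_problem(rng):
    """Noiseless linear mapping: decodable to R^2 = 1 by every family."""
    X = np.random.default_rng(3).standard_normal((600, 8))
    W = np.random.default_rng(4).standard_normal((8, 2))
    Y = X @ W + np.array([0.5, -1.0])
    return X, Y
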