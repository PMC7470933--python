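"""Synthetic spiking datasets with known ground truth.

Two generative modes emulate the statistics of typical electrophysiology
recordings used for decoding benchmarks, plus a plain linear-Gaussian
simulator used as an oracle for the Kalman filter:

* **cortical** — smooth, stationary 2-D velocity (a low-pass-filtered
  mean-reverting walk) drives cosine- and speed-tuned Poisson neurons:
  ``rate_i(t) = softplus(b0_i + m_i * speed * cos(theta - theta_pref_i)
  + s_i * speed)``.  Per-neuron target rates are drawn lognormal around a
  configurable population mean (default 6.7 spikes/s with median ~3.4,
  counted in 50 ms bins — the regime of a motor-cortex array recording), and
  the baseline ``b0_i`` is calibrated by bisection so each neuron hits its
  target mean rate.  The signed speed term and the softplus rectification
  make the encoding genuinely nonlinear in the decoded velocity.

* **hippocampal** — a reflected smoothed random walk on a bounded 2-D
  platform drives Gaussian place-field neurons:
  ``rate_i = peak_i * exp(-||pos - mu_i||^2 / (2 sigma_p^2)) + floor``.
  Per-neuron average rates are lognormal with the skew of real hippocampal
  populations (default mean ~1.7, median ~0.2 spikes/s in 200 ms bins):
  most neurons are nearly silent most of the time.

Spike times are drawn by sampling a Poisson count per bin at the bin-wise
rate and placing that many events uniformly within the bin.  Everything is
reproducible bit-for-bit from the integer seed, and the generative
parameters are returned for recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter1d

from spikedecode.data_format import SpikeData

__all__ = [
    "SyntheticGroundTruth",
    "simulate_cortical",
    "simulate_hippocampal",
    "simulate_linear_gaussian",
]


@dataclass
class SyntheticGroundTruth:
    """Generative parameters retained for parameter-recovery tests."""

    mode: str
    seed: int
    kinematics: dict[str, np.ndarray]
    tuning_params: dict[str, np.ndarray]
    rates: np.ndarray          # n_bins x N expected spikes/s per bin
    bin_size: float


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _spikes_from_rates(rates: np.ndarray, bin_size: float,
                       rng: np.random.Generator) -> SpikeData:
    """Poisson counts per bin, event times uniform within each bin."""
    n_bins, n_neurons = rates.shape
    counts = rng.poisson(rates * bin_size)
    spike_times = []
    for i in range(n_neurons):
        times = []
        nz = np.nonzero(counts[:, i])[0]
        for t in nz:
            times.append(t * bin_size + rng.random(counts[t, i]) * bin_size)
        st = np.sort(np.concatenate(times)) if times else np.empty(0)
        spike_times.append(st)
    return SpikeData(spike_times=spike_times, duration=n_bins * bin_size)


def _calibrate_baseline(drive: np.ndarray, target_rate: float) -> float:
    """Find b0 with mean(softplus(b0 + drive)) == target_rate (bisection)."""
    lo, hi = -50.0, 50.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _softplus(mid + drive).mean() < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _smooth_walk(n_bins: int, n_dims: int, smooth_bins: float,
                 rng: np.random.Generator,
                 mean_reversion: float = 0.1) -> np.ndarray:
    """Smoothed mean-reverting (Ornstein-Uhlenbeck) walk, unit variance.

    A pure random walk would drift, making held-out blocks statistically
    unlike the training data; the weak pull toward zero keeps the process
    stationary, like real cursor velocity.
    """
    rho = 1.0 - mean_reversion
    steps = rng.standard_normal((n_bins, n_dims))
    walk = np.empty_like(steps)
    acc = np.zeros(n_dims)
    for t in range(n_bins):
        acc = rho * acc + steps[t]
        walk[t] = acc
    walk = gaussian_filter1d(walk, smooth_bins, axis=0)
    walk -= walk.mean(axis=0)
    walk /= walk.std(axis=0)
    return walk


def simulate_cortical(
    n_neurons: int = 50,
    duration: float = 600.0,
    bin_size: float = 0.05,
    mean_rate: float = 6.7,
    median_rate: float = 3.4,
    tuning_depth: float = 2.0,
    speed_tuning: float = 2.0,
    smooth_bins: float = 8.0,
    seed: int = 0,
):
    """Cosine- and speed-tuned Poisson population driven by 2-D velocity.

    Each neuron follows the classic motor-cortex encoding model: a cosine
    dependence on movement direction scaled by speed (equivalently, a linear
    dependence on the velocity vector) plus a signed speed term,

        rate_i(t) = softplus(b0_i + m_i * speed * cos(theta - theta_pref_i)
                             + s_i * speed),

    with spikes Poisson given the rate.  The speed term and the softplus
    rectification make the encoding genuinely nonlinear in the decoded
    velocity, so nonlinear decoders have real structure to exploit.

    Parameters
    ----------
    tuning_depth
        Scales the directional modulation ``m_i``; with ``tuning_depth`` and
        ``speed_tuning`` both 0 the rates are independent of the kinematics
        (a pure-noise dataset on which every decoder should score ~0).
    speed_tuning
        Scales the signed speed coefficients ``s_i`` (positive and negative
        speed coding both occur in cortex).
    mean_rate, median_rate
        Population firing-rate targets in spikes/s (defaults match a
        motor-cortex array recording); per-neuron rates are lognormal with
        this mean and median, and the baseline ``b0_i`` is calibrated so
        each neuron attains its target mean rate.

    Returns ``(SpikeData, output_times, output_values, SyntheticGroundTruth)``
    where the outputs are the x/y velocity sampled at bin centers.
    """
    if min(n_neurons, duration, bin_size, mean_rate) <= 0:
        raise ValueError("n_neurons, duration, bin_size, mean_rate must be positive")
    rng = np.random.default_rng(seed)
    n_bins = int(np.floor(duration / bin_size + 1e-9))

    vel = _smooth_walk(n_bins, 2, smooth_bins, rng)
    speed = np.linalg.norm(vel, axis=1)
    theta = np.arctan2(vel[:, 1], vel[:, 0])

    theta_pref = rng.uniform(-np.pi, np.pi, n_neurons)
    # lognormal with the requested mean and median
    mu = np.log(max(median_rate, 1e-3))
    sigma2 = max(2.0 * (np.log(mean_rate) - mu), 1e-6)
    target = rng.lognormal(mu, np.sqrt(sigma2), n_neurons)
    target *= mean_rate / target.mean()  # pin the population mean exactly
    mod = tuning_depth * rng.uniform(1.0, 3.0, n_neurons)
    speed_mod = speed_tuning * rng.uniform(-3.0, 3.0, n_neurons)

    rates = np.empty((n_bins, n_neurons))
    b0 = np.empty(n_neurons)
    for i in range(n_neurons):
        drive = mod[i] * speed * np.cos(theta - theta_pref[i]) \
            + speed_mod[i] * speed
        b0[i] = _calibrate_baseline(drive, target[i])
        rates[:, i] = _softplus(b0[i] + drive)

    spikes = _spikes_from_rates(rates, bin_size, rng)
    achieved = spikes.total_spikes / duration / n_neurons
    if tuning_depth > 0 and abs(achieved - mean_rate) > 0.2 * mean_rate:
        warnings.warn(
            f"achieved mean rate {achieved:.2f} deviates >20% from target "
            f"{mean_rate}", stacklevel=2,
        )
    times = (np.arange(n_bins) + 0.5) * bin_size
    truth = SyntheticGroundTruth(
        mode="cortical", seed=seed,
        kinematics={"velocity": vel, "speed": speed, "direction": theta},
        tuning_params={
            "preferred_direction": theta_pref, "modulation": mod,
            "speed_modulation": speed_mod, "baseline": b0,
            "target_rate": target,
        },
        rates=rates, bin_size=bin_size,
    )
    return spikes, times, vel, truth


def simulate_hippocampal(
    n_neurons: int = 46,
    duration: float = 1200.0,
    bin_size: float = 0.2,
    box_size: float = 100.0,
    field_width: float = 10.0,
    mean_rate: float = 1.7,
    median_rate: float = 0.2,
    floor_rate: float = 0.02,
    smooth_bins: float = 5.0,
    seed: int = 0,
):
    """Gaussian place-field Poisson population on a bounded 2-D platform.

    The trajectory is a smoothed random walk reflected at the walls, with
    step size set so the per-bin displacement is about ``field_width / 5``.
    Per-neuron time-averaged rates are drawn lognormal with the requested
    population mean and median (hippocampal populations are strongly
    skewed: most cells are nearly silent outside a small field), and each
    neuron's field peak is calibrated against the trajectory's occupancy of
    its field so the neuron attains its target average rate.

    Returns ``(SpikeData, output_times, output_values, SyntheticGroundTruth)``
    where the outputs are the x/y position at bin centers.
    """
    if min(n_neurons, duration, bin_size, box_size, field_width) <= 0:
        raise ValueError("all size parameters must be positive")
    rng = np.random.default_rng(seed)
    n_bins = int(np.floor(duration / bin_size + 1e-9))

    step_sd = field_width / 5.0
    steps = gaussian_filter1d(
        rng.standard_normal((n_bins, 2)), smooth_bins, axis=0)
    steps *= step_sd / np.maximum(steps.std(axis=0), 1e-12)
    pos = np.cumsum(steps, axis=0) + box_size / 2.0
    # reflect into [0, box_size] (triangle-wave folding)
    pos = np.abs(np.mod(pos, 2.0 * box_size) - box_size)
    pos = box_size - pos

    centers = rng.uniform(0, box_size, (n_neurons, 2))
    # per-neuron average-rate targets: lognormal with the requested
    # population mean and median (mean/median ratio sets the skew)
    mu = np.log(max(median_rate, 1e-3))
    sigma2 = max(2.0 * (np.log(mean_rate) - mu), 1e-6)
    target = rng.lognormal(mu, np.sqrt(sigma2), n_neurons)
    target *= mean_rate / target.mean()
    d2 = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    profile = np.exp(-d2 / (2.0 * field_width ** 2))      # n_bins x N
    occupancy = np.maximum(profile.mean(axis=0), 1e-6)    # field dwell frac
    peaks = np.maximum(target - floor_rate, 0.0) / occupancy
    rates = peaks[None, :] * profile + floor_rate

    spikes = _spikes_from_rates(rates, bin_size, rng)
    times = (np.arange(n_bins) + 0.5) * bin_size
    truth = SyntheticGroundTruth(
        mode="hippocampal", seed=seed,
        kinematics={"position": pos},
        tuning_params={
            "field_center": centers, "field_width": np.full(n_neurons, field_width),
            "peak_rate": peaks, "floor_rate": np.full(n_neurons, floor_rate),
        },
        rates=rates, bin_size=bin_size,
    )
    return spikes, times, pos, truth


def simulate_linear_gaussian(
    A: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    Q: np.ndarray,
    T: int,
    x0: np.ndarray | None = None,
    seed: int = 0,
):
    """Exact draws from ``x_t = A x_{t-1} + w_t``, ``y_t = H x_t + q_t``.

    Oracle input generator for Kalman-filter equivalence and recovery
    tests.  ``w ~ N(0, W)`` and ``q ~ N(0, Q)``; ``x0`` defaults to zero.
    Warns when A is unstable (spectral radius > 1).
    """
    A, W, H, Q = (np.asarray(m, dtype=float) for m in (A, W, H, Q))
    s, n_obs = A.shape[0], H.shape[0]
    if np.max(np.abs(np.linalg.eigvals(A))) > 1.0 + 1e-9:
        warnings.warn("transition matrix A is unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    Lw = np.linalg.cholesky(W + 1e-15 * np.eye(s))
    Lq = np.linalg.cholesky(Q + 1e-15 * np.eye(n_obs))
    states = np.empty((T, s))
    obs = np.empty((T, n_obs))
    x = np.zeros(s) if x0 is None else np.asarray(x0, dtype=float)
    for t in range(T):
        x = A @ x + Lw @ rng.standard_normal(s)
        states[t] = x
        obs[t] = H @ x + Lq @ rng.standard_normal(n_obs)
    return states, obs
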