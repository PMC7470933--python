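"""Decoders with explicit output structure: Kalman filter and Naive Bayes.

**Kalman filter.**  The hidden state is the kinematics itself — for each
output axis the position, velocity and acceleration (state dimension
``s = 3 d``).  Even when only position or velocity is to be reported, the
full kinematic stack is kept in the state because it improves prediction.
The state evolves linearly, ``x_t = A x_{t-1} + w`` with ``w ~ N(0, W)``,
and the spike counts are a linear readout, ``y_t = H x_t + q`` with
``q ~ N(0, Q)``.  ``A, W, H, Q`` are fitted by least squares / residual
covariances on training data, and decoding is the standard predict/update
recursion.  At decode time the transition noise is scaled by a tunable
factor ``noise_scale`` (C): C = 1 is the classical decoder, while larger C
lets the filter trust the spikes more than the smooth-kinematics prior —
a single extra hyperparameter that can improve accuracy substantially.

**Naive Bayes.**  A Bayesian population decoder: each neuron gets a tuning
curve (expected spike count per decoding window as a function of the output
value on a discretized grid), neurons are assumed conditionally independent
given the output, and Bayes' rule turns the encoding models into a decoder.
With Poisson spiking the log posterior of grid cell ``g`` given window
counts ``n_1..n_N`` is

    log P(g | n) = sum_i [ n_i log f_i(g) - f_i(g) ] + log P(g) + const,

optionally plus a Gaussian transition prior that penalizes jumps away from
the previously decoded value.  The prediction is the grid value at the
posterior argmax (ties broken toward the lowest grid index).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import gaussian_filter

from spikedecode.decoders.base import Decoder, register_decoder

__all__ = ["KalmanDecoder", "NaiveBayesDecoder", "kinematic_state"]


def kinematic_state(Y: np.ndarray, bin_size: float = 1.0) -> np.ndarray:
    """Stack [Y, dY, d2Y]: derivatives by central finite differences.

    Interior bins use central differences over the bin grid; the first and
    last bins use one-sided differences.  Returns a ``K x 3d`` matrix.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    vel = np.gradient(Y, bin_size, axis=0)
    acc = np.gradient(vel, bin_size, axis=0)
    return np.column_stack([Y, vel, acc])


@register_decoder
class KalmanDecoder(Decoder):
    """Kalman filter with a kinematic hidden state.

    Parameters
    ----------
    noise_scale
        Factor C multiplying the fitted transition-noise covariance W at
        decode time.  Tuned on the validation set; 1.0 recovers the
        classical formulation.
    lag
        Signed bin offset between neural observations and the state:
        ``lag > 0`` pairs the counts in bin ``t`` with the kinematics in bin
        ``t + lag`` (neural activity leading behavior).
    bin_size
        Bin width in seconds, used only to give the finite-difference
        derivatives physical units.
    """

    name = "kalman_filter"
    input_layout = "state_space"
    default_search_space = {"noise_scale": (0.1, 100.0), "lag": [-2, -1, 0, 1, 2]}

    def __init__(self, noise_scale: float = 1.0, lag: int = 0, bin_size: float = 1.0):
        if noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        self.noise_scale = float(noise_scale)
        self.lag = int(lag)
        self.bin_size = float(bin_size)

    # -- model estimation ---------------------------------------------------

    def _fit_system(self, states: np.ndarray, observations: np.ndarray) -> None:
        """Least-squares system identification of (A, W, H, Q)."""
        S, O = states, observations
        K, s = S.shape
        if K < s + 1:
            raise ValueError(f"need at least s+1={s + 1} time bins, got {K}")
        A, _, _, _ = np.linalg.lstsq(S[:-1], S[1:], rcond=None)
        self.A_ = A.T
        res_w = S[1:] - S[:-1] @ A
        self.W_ = res_w.T @ res_w / max(res_w.shape[0] - 1, 1)
        H, _, _, _ = np.linalg.lstsq(S, O, rcond=None)
        self.H_ = H.T
        res_q = O - S @ H
        self.Q_ = res_q.T @ res_q / max(res_q.shape[0] - 1, 1)
        self.init_mean_ = S.mean(axis=0)
        self.init_cov_ = np.cov(S.T) + 1e-9 * np.eye(s)

    def _align(self, counts: np.ndarray, states: np.ndarray):
        """Pair counts[t] with states[t + lag] by trimming the edges."""
        if self.lag > 0:
            return counts[: counts.shape[0] - self.lag], states[self.lag:]
        if self.lag < 0:
            return counts[-self.lag:], states[: states.shape[0] + self.lag]
        return counts, states

    def fit(self, counts: np.ndarray, outputs: np.ndarray) -> "KalmanDecoder":
        """Fit from concurrent-bin spike counts and the primary kinematics.

        ``outputs`` (K x d) is augmented with finite-difference velocity and
        acceleration to form the full state before system identification.
        """
        counts = np.asarray(counts, dtype=float)
        outputs = self._as_2d(outputs, counts.shape[0])
        self.n_outputs_ = outputs.shape[1]
        states = kinematic_state(outputs, self.bin_size)
        obs_al, st_al = self._align(counts, states)
        self._fit_system(st_al, obs_al)
        return self

    # -- decoding -----------------------------------------------------------

    def decode(
        self, counts: np.ndarray, return_covariances: bool = False
    ):
        """Run the filter; returns K x s filtered state means.

        The recursion starts from the training-set mean kinematics with the
        training-set state covariance, and uses ``noise_scale * W`` as the
        transition noise.
        """
        O = np.asarray(counts, dtype=float)
        A, W, H, Q = self.A_, self.noise_scale * self.W_, self.H_, self.Q_
        s = A.shape[0]
        x = self.init_mean_.copy()
        P = self.init_cov_.copy()
        means = np.empty((O.shape[0], s))
        covs = [] if return_covariances else None
        I = np.eye(s)
        for t in range(O.shape[0]):
            # predict
            x = A @ x
            P = A @ P @ A.T + W
            # update
            S_innov = H @ P @ H.T + Q
            K_gain = np.linalg.solve(S_innov.T, (P @ H.T).T).T
            x = x + K_gain @ (O[t] - H @ x)
            P = (I - K_gain @ H) @ P
            P = 0.5 * (P + P.T)
            eigmin = np.linalg.eigvalsh(P)[0]
            if eigmin < -1e-10:
                warnings.warn("state covariance lost PSD; eigenvalues clipped at 0",
                              stacklevel=2)
                vals, vecs = np.linalg.eigh(P)
                P = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
            means[t] = x
            if covs is not None:
                covs.append(P.copy())
        if covs is not None:
            return means, np.asarray(covs)
        return means

    def predict(self, counts: np.ndarray) -> np.ndarray:
        """Decode and return the primary-output block of the state.

        With ``lag != 0`` the state estimate for bin ``t`` is driven by the
        counts at ``t - lag``; the first/last ``|lag|`` bins are padded with
        the nearest estimate so predictions align with the output grid.
        """
        means = self.decode(counts)
        d = self.n_outputs_
        est = means[:, :d]
        if self.lag > 0:
            est = np.vstack([np.repeat(est[:1], self.lag, axis=0), est[:-self.lag]])
            est = est[: counts.shape[0]]
        elif self.lag < 0:
            k = -self.lag
            est = np.vstack([est[k:], np.repeat(est[-1:], k, axis=0)])
        return est


@register_decoder
class NaiveBayesDecoder(Decoder):
    """Bayesian population decoder with Poisson encoding models.

    Parameters
    ----------
    grid_resolution
        Number of grid cells per output dimension (default 100 in 1-D,
        30 per axis in 2-D — kept enumerable on a desk machine).
    smoothing_bandwidth
        Gaussian smoothing of tuning curves and occupancy prior, in grid
        cells.
    use_transition_prior
        Add a Gaussian penalty on the distance from the previously decoded
        value; its bandwidth defaults to the training data's per-bin
        displacement SD.
    transition_bandwidth
        Override for that bandwidth, in output units.
    rate_floor
        Lower bound on expected counts per window, preventing log(0) for
        never-observed (output, neuron) combinations.
    """

    name = "naive_bayes"
    input_layout = "state_space"
    default_search_space = {"smoothing_bandwidth": (0.5, 4.0)}

    def __init__(self, grid_resolution: int | None = None,
                 smoothing_bandwidth: float = 1.0,
                 use_transition_prior: bool = True,
                 transition_bandwidth: float | None = None,
                 rate_floor: float = 0.01):
        self.grid_resolution = grid_resolution
        self.smoothing_bandwidth = float(smoothing_bandwidth)
        self.use_transition_prior = bool(use_transition_prior)
        self.transition_bandwidth = transition_bandwidth
        self.rate_floor = float(rate_floor)

    # -- fitting ------------------------------------------------------------

    def _grid_index(self, Y: np.ndarray) -> np.ndarray:
        """Flattened grid-cell index of each output row (C-order)."""
        idx = np.zeros(Y.shape[0], dtype=int)
        for dim in range(Y.shape[1]):
            edges = self.edges_[dim]
            j = np.clip(np.digitize(Y[:, dim], edges) - 1, 0, len(edges) - 2)
            idx = idx * (len(edges) - 1) + j
        return idx

    def fit(self, counts: np.ndarray, outputs: np.ndarray) -> "NaiveBayesDecoder":
        """Estimate tuning curves and the occupancy prior.

        ``counts`` are spike counts per decoding window (K x N); the tuning
        curves are therefore in expected-counts-per-window units and need no
        further time scaling at decode time.
        """
        counts = np.asarray(counts, dtype=float)
        Y = self._as_2d(outputs, counts.shape[0])
        if counts.shape[0] == 0:
            raise ValueError("empty training set")
        d = Y.shape[1]
        G_per = self.grid_resolution or (100 if d == 1 else 30)
        self.shape_ = (G_per,) * d
        self.edges_ = []
        centers = []
        for dim in range(d):
            lo, hi = Y[:, dim].min(), Y[:, dim].max()
            if hi == lo:
                hi = lo + 1e-6
            e = np.linspace(lo, hi, G_per + 1)
            self.edges_.append(e)
            centers.append(0.5 * (e[:-1] + e[1:]))
        mesh = np.meshgrid(*centers, indexing="ij")
        self.grid_values_ = np.column_stack([m.ravel() for m in mesh])  # G x d

        idx = self._grid_index(Y)
        G = int(np.prod(self.shape_))
        occupancy = np.bincount(idx, minlength=G).astype(float)
        N = counts.shape[1]
        sums = np.zeros((N, G))
        for i in range(N):
            sums[i] = np.bincount(idx, weights=counts[:, i], minlength=G)
        # smooth numerator and denominator separately so empty cells borrow
        # from their neighbors before the ratio is taken
        bw = self.smoothing_bandwidth
        occ_s = gaussian_filter(occupancy.reshape(self.shape_), bw).ravel()
        tuning = np.empty_like(sums)
        for i in range(N):
            num = gaussian_filter(sums[i].reshape(self.shape_), bw).ravel()
            tuning[i] = num / np.maximum(occ_s, 1e-12)
        self.tuning_ = np.maximum(tuning, self.rate_floor)
        prior = np.maximum(occ_s, 0.0)
        self.prior_ = prior / prior.sum()

        if self.transition_bandwidth is not None:
            self.transition_bw_ = float(self.transition_bandwidth)
        else:
            disp = np.diff(Y, axis=0)
            self.transition_bw_ = float(np.sqrt(np.mean(disp ** 2))) if len(disp) else 1.0
        self.transition_bw_ = max(self.transition_bw_, 1e-9)
        return self

    # -- decoding -----------------------------------------------------------

    def log_posterior(self, counts: np.ndarray) -> np.ndarray:
        """Unnormalized log posterior over the grid, one row per window."""
        counts = np.atleast_2d(np.asarray(counts, dtype=float))
        logf = np.log(self.tuning_)                       # N x G
        ll = counts @ logf - self.tuning_.sum(axis=0)     # K x G
        logp = ll + np.log(np.maximum(self.prior_, 1e-300))
        if not np.isfinite(logp).all():
            raise FloatingPointError("non-finite log posterior")
        return logp

    def decode(self, counts: np.ndarray,
               use_transition_prior: bool | None = None) -> np.ndarray:
        """Argmax decoding, optionally with the Gaussian transition prior."""
        use_tp = self.use_transition_prior if use_transition_prior is None \
            else use_transition_prior
        logp = self.log_posterior(counts)
        if not use_tp:
            best = np.argmax(logp, axis=1)
            return self.grid_values_[best]
        out = np.empty((logp.shape[0], self.grid_values_.shape[1]))
        prev = None
        two_bw2 = 2.0 * self.transition_bw_ ** 2
        for t in range(logp.shape[0]):
            row = logp[t]
            if prev is not None:
                dist2 = np.sum((self.grid_values_ - prev) ** 2, axis=1)
                row = row - dist2 / two_bw2
            g = int(np.argmax(row))
            prev = self.grid_values_[g]
            out[t] = prev
        return out

    def predict(self, counts: np.ndarray) -> np.ndarray:
        return self.decode(counts)
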