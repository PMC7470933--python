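"""Kalman filter and Naive Bayes against brute-force probabilistic oracles."""

import numpy as np
import pytest

from spikedecode.decoders import KalmanDecoder, NaiveBayesDecoder
from spikedecode.decoders.state_space import kinematic_state
from spikedecode.evaluation import r2_score
from spikedecode.synthetic import simulate_linear_gaussian


def joint_gaussian_filter_oracle(A, W, H, Q, m0, P0, observations):
    """Filtered means by explicit joint-Gaussian conditioning.

    Builds the full joint covariance of (x_1..x_T, y_1..y_T) implied by the
    linear-Gaussian model with x_1 ~ N(A m0, A P0 A^T + W), then for each t
    conditions x_t on y_1..y_t.  O(T^3) — tiny instances only.
    """
    T = observations.shape[0]
    s, n = A.shape[0], H.shape[0]
    # state means and cross-time covariances
    mx = np.empty((T, s))
    Pxx = np.empty((T, T, s, s))
    mx[0] = A @ m0
    Pxx[0, 0] = A @ P0 @ A.T + W
    for t in range(1, T):
        mx[t] = A @ mx[t - 1]
        Pxx[t, t] = A @ Pxx[t - 1, t - 1] @ A.T + W
    for i in range(T):
        for j in range(i + 1, T):
            Pxx[i, j] = Pxx[i, i] @ np.linalg.matrix_power(A, j - i).T
            Pxx[j, i] = Pxx[i, j].T
    my = (H @ mx.T).T
    Pyy = np.empty((T, T, n, n))
    Pxy = np.empty((T, T, s, n))
    for i in range(T):
        for j in range(T):
            Pyy[i, j] = H @ Pxx[i, j] @ H.T + (Q if i == j else 0)
            Pxy[i, j] = Pxx[i, j] @ H.T
    means = np.empty((T, s))
    for t in range(T):
        ny = (t + 1) * n
        Syy = np.block([[Pyy[i, j] for j in range(t + 1)] for i in range(t + 1)])
        Sxy = np.hstack([Pxy[t, j] for j in range(t + 1)])
        resid = (observations[: t + 1] - my[: t + 1]).ravel()
        means[t] = mx[t] + Sxy @ np.linalg.solve(Syy, resid)
    return means


def random_system(rng, s, n):
    A = rng.standard_normal((s, s))
    A *= 0.9 / max(np.abs(np.linalg.eigvals(A)).max(), 1e-6)
    Lw = rng.standard_normal((s, s)) * 0.3
    W = Lw @ Lw.T + 0.05 * np.eye(s)
    H = rng.standard_normal((n, s))
    Lq = rng.standard_normal((n, n)) * 0.3
    Q = Lq @ Lq.T + 0.05 * np.eye(n)
    return A, W, H, Q


class TestKalmanFit:
    def test_noiseless_transition_recovered_exactly(self):
        A0 = np.array([[0.9, 0.1], [-0.05, 0.8]])
        x = np.array([1.0, -1.0])
        states = np.empty((50, 2))
        for t in range(50):
            states[t] = x
            x = A0 @ x
        dec = KalmanDecoder()
        dec._fit_system(states, np.zeros((50, 3)))
        assert np.allclose(dec.A_, A0, atol=1e-8)
        assert np.allclose(dec.W_, 0, atol=1e-10)

    def test_recovery_from_long_noisy_simulation(self):
        rng = np.random.default_rng(5)
        A0 = np.array([[0.95, 0.05], [0.0, 0.9]])
        W0 = 0.01 * np.eye(2)
        H0 = rng.standard_normal((4, 2))
        Q0 = 0.1 * np.eye(4)
        states, obs = simulate_linear_gaussian(A0, W0, H0, Q0, T=10_000, seed=6)
        dec = KalmanDecoder()
        dec._fit_system(states, obs)
        assert np.max(np.abs(dec.A_ - A0)) < 0.05
        assert np.max(np.abs(dec.H_ - H0)) < 0.05

    def test_kinematic_state_is_six_dimensional_for_2d_output(self, rng):
        Y = rng.standard_normal((40, 2))
        S = kinematic_state(Y, 0.05)
        assert S.shape == (40, 6)
        # interior velocity is the central difference of position
        j, t = 0, 10
        assert S[t, 2 + j] == pytest.approx((Y[t + 1, j] - Y[t - 1, j]) / 0.1)

    def test_insufficient_data_rejected(self):
        dec = KalmanDecoder()
        with pytest.raises(ValueError, match="time bins"):
            dec._fit_system(np.zeros((3, 4)), np.zeros((3, 2)))


class TestKalmanDecode:
    def test_filtered_means_match_joint_gaussian_oracle(self):
        """Randomized equivalence with explicit conditioning, T <= 5."""
        rng = np.random.default_rng(11)
        for trial in range(20):
            s = int(rng.integers(1, 5))
            n = int(rng.integers(1, 4))
            T = int(rng.integers(2, 6))
            A, W, H, Q = random_system(rng, s, n)
            m0 = rng.standard_normal(s)
            P0 = np.eye(s) * 0.5
            obs = rng.standard_normal((T, n))
            dec = KalmanDecoder(noise_scale=1.0)
            dec.A_, dec.W_, dec.H_, dec.Q_ = A, W, H, Q
            dec.init_mean_, dec.init_cov_ = m0, P0
            means = dec.decode(obs)
            oracle = joint_gaussian_filter_oracle(A, W, H, Q, m0, P0, obs)
            assert np.allclose(means, oracle, atol=1e-6), f"trial {trial}"

    def test_uninformative_observations_follow_prior_dynamics(self):
        A = np.array([[0.9]])
        dec = KalmanDecoder()
        dec.A_, dec.W_ = A, np.array([[0.01]])
        dec.H_, dec.Q_ = np.array([[1.0]]), np.array([[1e12]])  # Q -> infinity
        dec.init_mean_, dec.init_cov_ = np.array([2.0]), np.array([[0.1]])
        means = dec.decode(np.ones((5, 1)) * 100.0)
        expected = [2.0 * 0.9 ** (t + 1) for t in range(5)]
        assert np.allclose(means[:, 0], expected, atol=1e-3)

    def test_noise_scale_changes_estimates(self):
        states, obs = simulate_linear_gaussian(
            np.array([[0.9]]), np.array([[0.05]]), np.array([[2.0]]),
            np.array([[1.0]]), T=100, seed=3)
        d1 = KalmanDecoder(noise_scale=1.0).fit(obs, states[:, [0]])
        d2 = KalmanDecoder(noise_scale=50.0).fit(obs, states[:, [0]])
        assert not np.allclose(d1.predict(obs), d2.predict(obs))

    def test_fitted_parameters_decode_nearly_as_well_as_truth(self):
        """On linear-Gaussian data, fitted-vs-true decode R2 gap < 0.05."""
        rng = np.random.default_rng(21)
        s, n = 2, 8
        A = np.array([[0.98, 0.02], [-0.01, 0.95]])
        W = 0.02 * np.eye(s)
        H = rng.standard_normal((n, s))
        Q = 0.5 * np.eye(n)
        states, obs = simulate_linear_gaussian(A, W, H, Q, T=4000, seed=22)
        half = 2000
        true_dec = KalmanDecoder()
        true_dec.A_, true_dec.W_, true_dec.H_, true_dec.Q_ = A, W, H, Q
        true_dec.init_mean_ = states[:half].mean(axis=0)
        true_dec.init_cov_ = np.cov(states[:half].T)
        fit_dec = KalmanDecoder()
        fit_dec._fit_system(states[:half], obs[:half])
        r2_true = r2_score(states[half:], true_dec.decode(obs[half:]))
        r2_fit = r2_score(states[half:], fit_dec.decode(obs[half:]))
        assert abs(r2_fit - r2_true) < 0.05


def nb_enumeration_oracle(model, counts_row, prev=None):
    """Exhaustive posterior enumeration in plain probability space."""
    G = model.grid_values_.shape[0]
    post = np.empty(G)
    for g in range(G):
        f = model.tuning_[:, g]
        loglik = np.sum(counts_row * np.log(f) - f)
        logprior = np.log(model.prior_[g]) if model.prior_[g] > 0 else -np.inf
        post[g] = loglik + logprior
        if prev is not None:
            d2 = np.sum((model.grid_values_[g] - prev) ** 2)
            post[g] -= d2 / (2 * model.transition_bw_ ** 2)
    return int(np.argmax(post))


class TestNaiveBayes:
    def _small_model(self, rng, n_neurons=4, G=25, K=400, d=1):
        Y = rng.uniform(0, 10, (K, d))
        rates = rng.uniform(0.5, 5.0, (K, n_neurons))
        counts = rng.poisson(rates)
        nb = NaiveBayesDecoder(grid_resolution=G if d == 1 else 5,
                               use_transition_prior=False)
        nb.fit(counts, Y)
        return nb, counts, Y

    def test_tuning_peaks_where_neuron_fires(self, rng):
        Y = np.linspace(0, 1, 500)[:, None]
        counts = np.zeros((500, 1))
        counts[(Y[:, 0] > 0.45) & (Y[:, 0] < 0.55), 0] = 8.0
        nb = NaiveBayesDecoder(grid_resolution=20, use_transition_prior=False)
        nb.fit(counts, Y)
        peak_cell = np.argmax(nb.tuning_[0])
        assert abs(nb.grid_values_[peak_cell, 0] - 0.5) < 0.1

    def test_uniform_firing_gives_flat_tuning(self, rng):
        Y = rng.uniform(0, 1, (2000, 1))
        counts = np.full((2000, 1), 3.0)
        nb = NaiveBayesDecoder(grid_resolution=10, use_transition_prior=False)
        nb.fit(counts, Y)
        assert np.ptp(nb.tuning_[0]) < 0.5

    def test_argmax_matches_enumeration_oracle(self, rng):
        nb, counts, _ = self._small_model(rng)
        decoded = nb.decode(counts[:50], use_transition_prior=False)
        for k in range(50):
            g = nb_enumeration_oracle(nb, counts[k])
            assert np.allclose(decoded[k], nb.grid_values_[g])

    def test_argmax_matches_enumeration_oracle_2d(self, rng):
        nb, counts, _ = self._small_model(rng, d=2)  # 5x5 grid
        decoded = nb.decode(counts[:30], use_transition_prior=False)
        for k in range(30):
            g = nb_enumeration_oracle(nb, counts[k])
            assert np.allclose(decoded[k], nb.grid_values_[g])

    def test_transition_prior_matches_sequential_oracle(self, rng):
        nb, counts, _ = self._small_model(rng)
        decoded = nb.decode(counts[:30], use_transition_prior=True)
        prev = None
        for k in range(30):
            g = nb_enumeration_oracle(nb, counts[k], prev=prev)
            prev = nb.grid_values_[g]
            assert np.allclose(decoded[k], prev)

    def test_degenerate_prior_dominates(self, rng):
        nb, counts, _ = self._small_model(rng)
        nb.prior_ = np.zeros(nb.prior_.shape)
        nb.prior_[7] = 1.0
        decoded = nb.decode(counts[:20], use_transition_prior=False)
        assert np.allclose(decoded, nb.grid_values_[7])

    def test_log_posterior_finite_for_large_counts(self, rng):
        nb, counts, _ = self._small_model(rng)
        big = np.full((3, counts.shape[1]), 1e4)
        assert np.isfinite(nb.log_posterior(big)).all()

    def test_posterior_normalizes_to_one(self, rng):
        nb, counts, _ = self._small_model(rng)
        logp = nb.log_posterior(counts[:10])
        p = np.exp(logp - logp.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_flat_prior_single_neuron_reduces_to_ml_inversion(self, rng):
        """With a flat prior and one neuron, decoding is ML tuning inversion."""
        nb, counts, _ = self._small_model(rng, n_neurons=1)
        nb.prior_ = np.full(nb.prior_.shape, 1.0 / nb.prior_.size)
        decoded = nb.decode(counts[:40], use_transition_prior=False)
        for k in range(40):
            n = counts[k, 0]
            f = nb.tuning_[0]
            ml = np.argmax(n * np.log(f) - f)
            assert np.allclose(decoded[k], nb.grid_values_[ml])

    def test_place_field_center_recovery(self):
        """Simulated Gaussian place cell: peak within one grid cell of mu."""
        rng = np.random.default_rng(33)
        K = 10_000
        pos = rng.uniform(0, 100, (K, 1))
        mu, sigma = 42.0, 8.0
        rates = 10.0 * np.exp(-((pos[:, 0] - mu) ** 2) / (2 * sigma ** 2)) + 0.05
        counts = rng.poisson(rates)[:, None]
        nb = NaiveBayesDecoder(grid_resolution=50, use_transition_prior=False)
        nb.fit(counts, pos)
        cell_width = 100.0 / 50
        peak = nb.grid_values_[np.argmax(nb.tuning_[0]), 0]
        assert abs(peak - mu) <= cell_width

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            NaiveBayesDecoder().fit(np.zeros((0, 2)), np.zeros((0, 1)))
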