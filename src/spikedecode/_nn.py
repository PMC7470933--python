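"""Minimal numpy neural networks for decoding.

Implements exactly what the decoders need and nothing more: a feedforward
multilayer perceptron with dropout, and single-layer simple-RNN / GRU / LSTM
sequence regressors that read a ``B``-step window of population activity and
predict from the final hidden state.  All models are trained with Adam on a
mean-squared-error loss (summed over output dimensions, averaged over rows),
with gradients computed by hand-written backpropagation (through time, for
the recurrent cells).  Gradient correctness is pinned down by
finite-difference checks in the test suite.

Everything is deterministic given the integer seed: weight initialization,
minibatch shuffling and dropout masks all come from one ``Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLPRegressor", "RecurrentRegressor"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[:n, :m] if n >= m else q[:m, :n].T


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _clip_global(grads: list[np.ndarray], max_norm: float = 5.0) -> list[np.ndarray]:
    norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        grads = [g * scale for g in grads]
    return grads


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


class MLPRegressor:
    """Feedforward network: ``n_layers`` equal-width ReLU hidden layers with
    dropout after each, then a linear readout of all ``d`` outputs jointly.
    """

    def __init__(self, units: int = 400, n_layers: int = 2, dropout: float = 0.0,
                 epochs: int = 10, batch_size: int = 128, lr: float = 1e-3,
                 seed: int = 0):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.units = int(units)
        self.n_layers = int(n_layers)
        self.dropout = float(dropout)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.lr = float(lr)
        self.seed = int(seed)

    # -- forward/backward ---------------------------------------------------

    def _forward(self, X, rng=None):
        """Return (prediction, cache).  Training mode iff rng is given."""
        a = X
        cache = []
        for W, b in self.hidden_:
            z = a @ W + b
            h = np.maximum(z, 0.0)
            if rng is not None and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * mask
            else:
                mask = None
            cache.append((a, z, mask))
            a = h
        Wo, bo = self.out_
        return a @ Wo + bo, (cache, a)

    def _backward(self, X, dY, fwd_cache):
        cache, a_last = fwd_cache
        Wo, bo = self.out_
        grads_out = [a_last.T @ dY, dY.sum(axis=0)]
        da = dY @ Wo.T
        grads_hidden = []
        for (a_in, z, mask), (W, b) in zip(reversed(cache), reversed(self.hidden_)):
            if mask is not None:
                da = da * mask
            dz = da * (z > 0)
            grads_hidden.append((a_in.T @ dz, dz.sum(axis=0)))
            da = dz @ W.T
        grads = []
        for gW, gb in reversed(grads_hidden):
            grads.extend([gW, gb])
        grads.extend(grads_out)
        return grads

    # -- public API ---------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "MLPRegressor":
        X = np.asarray(X, dtype=float)
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] == 1 and X.shape[0] != 1:
            Y = Y.T
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("non-finite values in training data")
        rng = np.random.default_rng(self.seed)
        n_in, d = X.shape[1], Y.shape[1]
        self.hidden_ = []
        fan = n_in
        for _ in range(self.n_layers):
            self.hidden_.append([_glorot(rng, fan, self.units), np.zeros(self.units)])
            fan = self.units
        self.out_ = [_glorot(rng, fan, d), np.zeros(d)]
        params = [p for layer in self.hidden_ for p in layer] + self.out_
        opt = _Adam(params, lr=self.lr)
        for _ in range(self.epochs):
            for idx in _minibatches(X.shape[0], self.batch_size, rng):
                xb, yb = X[idx], Y[idx]
                pred, fwd = self._forward(xb, rng=rng)
                # d/dpred of mean-over-rows sum-over-dims squared error
                dY = 2.0 * (pred - yb) / xb.shape[0]
                grads = self._backward(xb, dY, fwd)
                opt.step(_clip_global(grads))
        last = float(np.mean(np.sum((self.predict(X) - Y) ** 2, axis=1)))
        if not np.isfinite(last):
            raise RuntimeError(f"training diverged (final loss {last})")
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        pred, _ = self._forward(np.asarray(X, dtype=float), rng=None)
        return pred


class RecurrentRegressor:
    """Single-layer recurrent sequence regressor (simple RNN, GRU or LSTM).

    Consumes a ``K x N x B`` tensor; the cell is run over the ``B`` time
    steps and the final hidden state is linearly mapped to the ``d`` outputs.
    Dropout, when requested, is applied to the input-to-hidden contribution
    at every step during training (inverted dropout).
    """

    def __init__(self, cell: str = "lstm", units: int = 100, dropout: float = 0.0,
                 epochs: int = 10, batch_size: int = 128, lr: float = 1e-3,
                 seed: int = 0):
        if cell not in ("rnn", "gru", "lstm"):
            raise ValueError(f"unknown cell {cell!r}")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.cell = cell
        self.units = int(units)
        self.dropout = float(dropout)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.lr = float(lr)
        self.seed = int(seed)

    # number of stacked gate blocks per cell type
    _GATES = {"rnn": 1, "gru": 3, "lstm": 4}

    def _init_params(self, rng, n_in, d):
        g = self._GATES[self.cell]
        H = self.units
        self.Wx_ = np.concatenate([_glorot(rng, n_in, H) for _ in range(g)], axis=1)
        self.Wh_ = np.concatenate([_orthogonal(rng, H, H) for _ in range(g)], axis=1)
        self.b_ = np.zeros(g * H)
        if self.cell == "lstm":
            self.b_[H:2 * H] = 1.0  # forget-gate bias: remember by default
        self.Wo_ = _glorot(rng, H, d)
        self.bo_ = np.zeros(d)

    @property
    def _params(self):
        return [self.Wx_, self.Wh_, self.b_, self.Wo_, self.bo_]

    # -- cell forward steps -------------------------------------------------

    def _step(self, x, h, c):
        """One time step; returns (h_new, c_new, cache)."""
        H = self.units
        zx = x @ self.Wx_
        if self.cell == "rnn":
            s = zx + h @ self.Wh_ + self.b_
            h_new = np.tanh(s)
            return h_new, None, (x, h, h_new)
        if self.cell == "gru":
            # gates: update z, reset r, candidate n (reset applied to state
            # before the recurrent matmul)
            hz = h @ self.Wh_[:, :H]
            hr = h @ self.Wh_[:, H:2 * H]
            z = _sigmoid(zx[:, :H] + hz + self.b_[:H])
            r = _sigmoid(zx[:, H:2 * H] + hr + self.b_[H:2 * H])
            rh = r * h
            n = np.tanh(zx[:, 2 * H:] + rh @ self.Wh_[:, 2 * H:] + self.b_[2 * H:])
            h_new = (1 - z) * n + z * h
            return h_new, None, (x, h, z, r, rh, n)
        # lstm: input i, forget f, candidate g, output o
        s = zx + h @ self.Wh_ + self.b_
        i = _sigmoid(s[:, :H])
        f = _sigmoid(s[:, H:2 * H])
        gg = np.tanh(s[:, 2 * H:3 * H])
        o = _sigmoid(s[:, 3 * H:])
        c_new = f * c + i * gg
        tc = np.tanh(c_new)
        h_new = o * tc
        return h_new, c_new, (x, h, c, i, f, gg, o, tc)

    def _forward(self, X3, rng=None):
        K, N, B = X3.shape
        H = self.units
        h = np.zeros((K, H))
        c = np.zeros((K, H)) if self.cell == "lstm" else None
        caches = []
        for t in range(B):
            x = X3[:, :, t]
            if rng is not None and self.dropout > 0:
                mask = (rng.random(x.shape) >= self.dropout) / (1 - self.dropout)
                x = x * mask
            h, c, cache = self._step(x, h, c)
            caches.append(cache)
        pred = h @ self.Wo_ + self.bo_
        return pred, (caches, h)

    # -- backward through time ---------------------------------------------

    def _backward(self, dY, fwd_cache):
        caches, h_last = fwd_cache
        H = self.units
        gWx = np.zeros_like(self.Wx_)
        gWh = np.zeros_like(self.Wh_)
        gb = np.zeros_like(self.b_)
        gWo = h_last.T @ dY
        gbo = dY.sum(axis=0)
        dh = dY @ self.Wo_.T
        dc = None
        for cache in reversed(caches):
            if self.cell == "rnn":
                x, h_prev, h_new = cache
                ds = dh * (1 - h_new ** 2)
                gWx += x.T @ ds
                gWh += h_prev.T @ ds
                gb += ds.sum(axis=0)
                dh = ds @ self.Wh_.T
            elif self.cell == "gru":
                x, h_prev, z, r, rh, n = cache
                dn = dh * (1 - z)
                dz = dh * (h_prev - n)
                dh_prev = dh * z
                dsn = dn * (1 - n ** 2)
                gWx[:, 2 * H:] += x.T @ dsn
                gWh[:, 2 * H:] += rh.T @ dsn
                gb[2 * H:] += dsn.sum(axis=0)
                drh = dsn @ self.Wh_[:, 2 * H:].T
                dr = drh * h_prev
                dh_prev += drh * r
                dsz = dz * z * (1 - z)
                dsr = dr * r * (1 - r)
                gWx[:, :H] += x.T @ dsz
                gWx[:, H:2 * H] += x.T @ dsr
                gWh[:, :H] += h_prev.T @ dsz
                gWh[:, H:2 * H] += h_prev.T @ dsr
                gb[:H] += dsz.sum(axis=0)
                gb[H:2 * H] += dsr.sum(axis=0)
                dh_prev += dsz @ self.Wh_[:, :H].T + dsr @ self.Wh_[:, H:2 * H].T
                dh = dh_prev
            else:  # lstm
                x, h_prev, c_prev, i, f, gg, o, tc = cache
                if dc is None:
                    dc = np.zeros_like(dh)
                do = dh * tc
                dc = dc + dh * o * (1 - tc ** 2)
                di = dc * gg
                df = dc * c_prev
                dgg = dc * i
                dc_prev = dc * f
                ds = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f),
                     dgg * (1 - gg ** 2), do * o * (1 - o)], axis=1)
                gWx += x.T @ ds
                gWh += h_prev.T @ ds
                gb += ds.sum(axis=0)
                dh = ds @ self.Wh_.T
                dc = dc_prev
        return [gWx, gWh, gb, gWo, gbo]

    # -- public API ---------------------------------------------------------

    def fit(self, X3: np.ndarray, Y: np.ndarray) -> "RecurrentRegressor":
        X3 = np.asarray(X3, dtype=float)
        if X3.ndim != 3:
            raise ValueError("recurrent decoders require a K x N x B tensor")
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] == 1 and X3.shape[0] != 1:
            Y = Y.T
        if not (np.isfinite(X3).all() and np.isfinite(Y).all()):
            raise ValueError("non-finite values in training data")
        rng = np.random.default_rng(self.seed)
        self._init_params(rng, X3.shape[1], Y.shape[1])
        opt = _Adam(self._params, lr=self.lr)
        for _ in range(self.epochs):
            for idx in _minibatches(X3.shape[0], self.batch_size, rng):
                xb, yb = X3[idx], Y[idx]
                pred, fwd = self._forward(xb, rng=rng)
                dY = 2.0 * (pred - yb) / xb.shape[0]
                grads = self._backward(dY, fwd)
                opt.step(_clip_global(grads))
        last = float(np.mean(np.sum((self.predict(X3) - Y) ** 2, axis=1)))
        if not np.isfinite(last):
            raise RuntimeError(f"training diverged (final loss {last})")
        return self

    def predict(self, X3: np.ndarray) -> np.ndarray:
        pred, _ = self._forward(np.asarray(X3, dtype=float), rng=None)
        return pred
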