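"""Wiener filter and Wiener cascade.

The Wiener filter is multiple linear regression from the lagged spike counts
to the output: with an intercept column prepended, the weights are the
ordinary least-squares solution of ``[1 X] w = Y``.  The Wiener cascade
(linear-nonlinear model) follows the linear stage with a static polynomial
fitted, per output dimension, from the linear stage's training predictions to
the training outputs; the nonlinearity is a function of the linear output
only, so there is no nonlinear mixing of input features.
"""

from __future__ import annotations

import warnings

import numpy as np

from spikedecode.decoders.base import Decoder, register_decoder

__all__ = ["WienerFilterDecoder", "WienerCascadeDecoder"]


def _solve_ols(X: np.ndarray, Y: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Least-squares weights of ``[1 X] w = Y``, shape (p+1, d).

    Rank-deficient systems get the least-norm solution (with a warning).
    ``ridge > 0`` adds an L2 penalty on the non-intercept weights.
    """
    K, p = X.shape
    A = np.column_stack([np.ones(K), X])
    if ridge > 0.0:
        pen = np.sqrt(ridge) * np.eye(p + 1)
        pen[0, 0] = 0.0  # intercept unpenalized
        A_aug = np.vstack([A, pen])
        Y_aug = np.vstack([Y, np.zeros((p + 1, Y.shape[1]))])
        w, _, rank, _ = np.linalg.lstsq(A_aug, Y_aug, rcond=None)
        return w
    w, _, rank, _ = np.linalg.lstsq(A, Y, rcond=None)
    if rank < p + 1:
        warnings.warn(
            f"rank-deficient design ({rank} < {p + 1}); least-norm solution used",
            stacklevel=3,
        )
    return w


@register_decoder
class WienerFilterDecoder(Decoder):
    """Lagged multiple linear regression (optionally ridge-regularized).

    Parameters
    ----------
    ridge
        L2 penalty on the non-intercept weights; 0 (the default) is plain
        ordinary least squares.
    """

    name = "wiener_filter"
    input_layout = "flat"
    default_search_space = {"ridge": (0.0, 100.0)}

    def __init__(self, ridge: float = 0.0):
        self.ridge = float(ridge)

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "WienerFilterDecoder":
        X = np.asarray(X, dtype=float)
        Y = self._as_2d(Y, X.shape[0])
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("non-finite values in training data")
        if X.shape[0] <= X.shape[1]:
            warnings.warn(
                f"K={X.shape[0]} rows <= {X.shape[1]} features; fit is "
                "underdetermined", stacklevel=2,
            )
        self.weights_ = _solve_ols(X, Y, self.ridge)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.weights_[0] + X @ self.weights_[1:]


@register_decoder
class WienerCascadeDecoder(Decoder):
    """Linear stage + fitted static polynomial nonlinearity, per output.

    ``degree=1`` reduces to an affine re-fit of the linear stage, so the
    cascade's predictions then coincide with the Wiener filter's.  The
    polynomial is an ordinary least-squares fit on the Vandermonde expansion
    of the stage-1 training predictions, which guarantees the cascade's
    training MSE never exceeds the linear stage's.
    """

    name = "wiener_cascade"
    input_layout = "flat"
    default_search_space = {"degree": [1, 2, 3, 4, 5]}

    def __init__(self, degree: int = 3, ridge: float = 0.0):
        if degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        self.degree = int(degree)
        self.ridge = float(ridge)

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "WienerCascadeDecoder":
        X = np.asarray(X, dtype=float)
        Y = self._as_2d(Y, X.shape[0])
        if self.degree >= X.shape[0]:
            raise ValueError(
                f"degree {self.degree} >= number of training rows {X.shape[0]}"
            )
        self.linear_ = WienerFilterDecoder(ridge=self.ridge).fit(X, Y)
        Z = self.linear_.predict(X)
        # highest-power-first, one coefficient vector per output dimension
        self.poly_coeffs_ = [
            np.polyfit(Z[:, j], Y[:, j], self.degree) for j in range(Y.shape[1])
        ]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.linear_.predict(X)
        return np.column_stack(
            [np.polyval(c, Z[:, j]) for j, c in enumerate(self.poly_coeffs_)]
        )
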