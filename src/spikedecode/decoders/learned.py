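"""The six learned decoder families.

Support-vector regression (RBF kernel, scikit-learn) and gradient-boosted
regression trees (XGBoost) decode each output dimension independently from
the flat design matrix; the feedforward network and the three recurrent
networks (simple RNN, GRU, LSTM — in-package numpy implementations, see
``spikedecode._nn``) fit all output dimensions jointly.  All are trained to
minimize mean squared error.  SVR z-scores its target internally and
inverse-transforms predictions, which helps the epsilon-insensitive loss;
every other family consumes the outputs as given.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVR
from xgboost import XGBRegressor

from spikedecode._nn import MLPRegressor, RecurrentRegressor
from spikedecode.data_format import fit_scaler
from spikedecode.decoders.base import Decoder, register_decoder

__all__ = [
    "SVRDecoder",
    "XGBoostDecoder",
    "FeedforwardDecoder",
    "SimpleRNNDecoder",
    "GRUDecoder",
    "LSTMDecoder",
    "fit_learned",
    "predict_learned",
    "sweep_feedforward",
]


def _check_finite(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in decoder input")
    return X


@register_decoder
class SVRDecoder(Decoder):
    """RBF-kernel support vector regression, one model per output dimension.

    ``max_iter`` bounds the solver (−1 = run to convergence; the default cap
    keeps desk-scale fits fast at indistinguishable accuracy); the target is
    z-scored internally and predictions are returned in original units.
    """

    name = "svr"
    input_layout = "flat"
    default_search_space = {"C": (1.0, 1e4)}

    def __init__(self, C: float = 3.0, max_iter: int = 4000):
        self.C = float(C)
        self.max_iter = int(max_iter)

    def fit(self, X, Y):
        X = _check_finite(X)
        Y = self._as_2d(Y, X.shape[0])
        self.y_scaler_ = fit_scaler(Y, "zscore")
        Yz = self.y_scaler_.transform(Y)
        self.models_ = []
        for j in range(Y.shape[1]):
            m = SVR(kernel="rbf", C=self.C, max_iter=self.max_iter)
            m.fit(X, Yz[:, j])
            self.models_.append(m)
        return self

    def predict(self, X):
        X = _check_finite(X)
        Z = np.column_stack([m.predict(X) for m in self.models_])
        return self.y_scaler_.inverse_transform(Z)


@register_decoder
class XGBoostDecoder(Decoder):
    """Gradient-boosted regression trees, one model per output dimension."""

    name = "boosted_trees"
    input_layout = "flat"
    default_search_space = {
        "max_depth": [2, 3, 4, 5, 6, 7, 8],
        "n_estimators": (100, 1000),
        "learning_rate": (0.01, 0.3),
    }

    def __init__(self, max_depth: int = 4, n_estimators: int = 300,
                 learning_rate: float = 0.1, seed: int = 0):
        self.max_depth = int(max_depth)
        self.n_estimators = int(n_estimators)
        self.learning_rate = float(learning_rate)
        self.seed = int(seed)

    def fit(self, X, Y):
        X = _check_finite(X)
        Y = self._as_2d(Y, X.shape[0])
        self.models_ = []
        for j in range(Y.shape[1]):
            m = XGBRegressor(
                max_depth=self.max_depth,
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate,
                objective="reg:squarederror",
                random_state=self.seed,
                n_jobs=1,
                verbosity=0,
            )
            m.fit(X, Y[:, j])
            self.models_.append(m)
        return self

    def predict(self, X):
        X = _check_finite(X)
        return np.column_stack([m.predict(X) for m in self.models_])


@register_decoder
class FeedforwardDecoder(Decoder):
    """Feedforward net: two equal-width ReLU hidden layers with dropout.

    The three exposed hyperparameters are the number of units per layer, the
    dropout proportion, and the number of training epochs.
    """

    name = "feedforward"
    input_layout = "flat"
    default_search_space = {
        "units": (50, 1000),
        "dropout": (0.0, 0.5),
        "epochs": (2, 20),
    }

    def __init__(self, units: int = 400, dropout: float = 0.3, epochs: int = 10,
                 n_layers: int = 2, lr: float = 3e-3, seed: int = 0):
        self.units = int(units)
        self.dropout = float(dropout)
        self.epochs = int(epochs)
        self.n_layers = int(n_layers)
        self.lr = float(lr)
        self.seed = int(seed)

    def fit(self, X, Y):
        X = _check_finite(X)
        Y = self._as_2d(Y, X.shape[0])
        self.model_ = MLPRegressor(
            units=self.units, n_layers=self.n_layers, dropout=self.dropout,
            epochs=self.epochs, lr=self.lr, seed=self.seed,
        ).fit(X, Y)
        return self

    def predict(self, X):
        return self.model_.predict(_check_finite(X))


class _RecurrentDecoder(Decoder):
    """Shared wrapper for the three recurrent families."""

    input_layout = "sequence"
    cell = "rnn"
    default_search_space = {
        "units": (50, 1000),
        "dropout": (0.0, 0.5),
        "epochs": (2, 20),
    }

    def __init__(self, units: int = 100, dropout: float = 0.3, epochs: int = 10,
                 lr: float = 3e-3, seed: int = 0):
        self.units = int(units)
        self.dropout = float(dropout)
        self.epochs = int(epochs)
        self.lr = float(lr)
        self.seed = int(seed)

    def fit(self, X3, Y):
        X3 = _check_finite(X3)
        if X3.ndim != 3:
            raise ValueError(
                f"{self.name} requires a K x N x B sequence tensor, got "
                f"{X3.ndim}-d input"
            )
        Y = self._as_2d(Y, X3.shape[0])
        self.model_ = RecurrentRegressor(
            cell=self.cell, units=self.units, dropout=self.dropout,
            epochs=self.epochs, lr=self.lr, seed=self.seed,
        ).fit(X3, Y)
        return self

    def predict(self, X3):
        return self.model_.predict(_check_finite(X3))


@register_decoder
class SimpleRNNDecoder(_RecurrentDecoder):
    """Simple recurrent network: tanh hidden state, linear readout of the
    final hidden state."""

    name = "rnn"
    cell = "rnn"


@register_decoder
class GRUDecoder(_RecurrentDecoder):
    """Gated recurrent unit network."""

    name = "gru"
    cell = "gru"


@register_decoder
class LSTMDecoder(_RecurrentDecoder):
    """Long short-term memory network."""

    name = "lstm"
    cell = "lstm"


def fit_learned(family: str, X: np.ndarray, Y: np.ndarray, **hyperparams) -> Decoder:
    """Fit one of the six learned families by name.

    Recurrent families require the sequence tensor, flat families the design
    matrix; a mismatched layout raises ``ValueError``.
    """
    from spikedecode.decoders.base import get_decoder

    dec = get_decoder(family, **hyperparams)
    X = np.asarray(X, dtype=float)
    if dec.input_layout == "flat" and X.ndim != 2:
        raise ValueError(f"{family} requires a flat K x (N*B) design matrix")
    return dec.fit(X, Y)


def predict_learned(decoder: Decoder, X: np.ndarray) -> np.ndarray:
    return decoder.predict(X)


def sweep_feedforward(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    units_list,
    dropout_list,
    fixed_epochs: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Hyperparameter-robustness surface for the feedforward decoder.

    Fits one network per (units, dropout) pair on a fixed training set with
    the number of epochs held constant, and returns the matrix of test-set
    R² values (rows = units, columns = dropout).
    """
    from spikedecode.evaluation import r2_score

    if not len(units_list) or not len(dropout_list):
        raise ValueError("units_list and dropout_list must be non-empty")
    surface = np.empty((len(units_list), len(dropout_list)))
    for a, units in enumerate(units_list):
        for b, dropout in enumerate(dropout_list):
            dec = FeedforwardDecoder(
                units=units, dropout=dropout, epochs=fixed_epochs, seed=seed,
            ).fit(X_train, Y_train)
            surface[a, b] = r2_score(Y_test, dec.predict(X_test))
    return surface
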