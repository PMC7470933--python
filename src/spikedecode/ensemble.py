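"""Stacked ensemble of the eight flat/sequence decoders.

The predictions of the eight base decoders (Wiener filter, Wiener cascade,
SVR, boosted trees, feedforward, simple RNN, GRU, LSTM — the Kalman filter
and Naive Bayes are excluded because their input formats differ) are
concatenated into a ``K x (8 d)`` matrix and fed to a second-tier regressor
("stacker") trained to predict the true output.  The default stacker is a
small feedforward network, with a linear least-squares stacker available;
the linear stacker can always reproduce any single base's predictions, so
its training R² is never below the best base's.

Stacker training data must come from rows the bases did not train on
(out-of-fold or validation predictions) — training the stacker on base
*training*-set predictions would reward overfit bases.  The cross-validation
driver in :mod:`spikedecode.evaluation` feeds validation-partition
predictions here.
"""

from __future__ import annotations

import numpy as np

from spikedecode._nn import MLPRegressor
from spikedecode.decoders.base import Decoder

__all__ = ["DEFAULT_BASE_FAMILIES", "EnsembleModel", "ensemble_fit", "ensemble_predict"]

DEFAULT_BASE_FAMILIES = (
    "wiener_filter",
    "wiener_cascade",
    "svr",
    "boosted_trees",
    "feedforward",
    "rnn",
    "gru",
    "lstm",
)


class EnsembleModel(Decoder):
    """Second-tier model over stacked base predictions.

    Parameters
    ----------
    stacker
        ``"feedforward"`` (default) or ``"linear"``.
    base_names
        Ordered base-decoder names; recorded for bookkeeping, the model
        itself only sees their stacked prediction columns.
    """

    name = "ensemble"
    input_layout = "stacked"

    def __init__(self, stacker: str = "feedforward",
                 base_names=DEFAULT_BASE_FAMILIES,
                 units: int = 100, epochs: int = 20, dropout: float = 0.0,
                 seed: int = 0):
        if stacker not in ("feedforward", "linear"):
            raise ValueError(f"unknown stacker {stacker!r}")
        self.stacker = stacker
        self.base_names = tuple(base_names)
        self.units = int(units)
        self.epochs = int(epochs)
        self.dropout = float(dropout)
        self.seed = int(seed)

    def fit(self, base_predictions: np.ndarray, Y: np.ndarray) -> "EnsembleModel":
        P = np.asarray(base_predictions, dtype=float)
        Y = self._as_2d(Y, P.shape[0])
        if P.shape[0] != Y.shape[0]:
            raise ValueError(
                f"base predictions have {P.shape[0]} rows but Y has {Y.shape[0]}"
            )
        if self.stacker == "linear":
            A = np.column_stack([np.ones(P.shape[0]), P])
            self.weights_, _, _, _ = np.linalg.lstsq(A, Y, rcond=None)
        else:
            self.model_ = MLPRegressor(
                units=self.units, n_layers=1, dropout=self.dropout,
                epochs=self.epochs, seed=self.seed,
            ).fit(P, Y)
        return self

    def predict(self, base_predictions: np.ndarray) -> np.ndarray:
        P = np.asarray(base_predictions, dtype=float)
        if self.stacker == "linear":
            return self.weights_[0] + P @ self.weights_[1:]
        return self.model_.predict(P)


def ensemble_fit(base_predictions: np.ndarray, Y: np.ndarray,
                 stacker: str = "feedforward", **kwargs) -> EnsembleModel:
    """Fit the second-tier model on held-out base predictions."""
    return EnsembleModel(stacker=stacker, **kwargs).fit(base_predictions, Y)


def ensemble_predict(model: EnsembleModel, base_predictions: np.ndarray) -> np.ndarray:
    return model.predict(base_predictions)


def stack_predictions(per_base: list[np.ndarray]) -> np.ndarray:
    """Column-concatenate base predictions in base order -> K x (n_bases*d)."""
    return np.column_stack([np.atleast_2d(p) for p in per_base])
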