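"""Uniform decoder contract and the name-keyed registry."""

from __future__ import annotations

from typing import Any

import numpy as np

__all__ = ["Decoder", "DECODER_REGISTRY", "register_decoder", "get_decoder"]


class Decoder:
    """Base class: ``fit(X, Y) -> self``, ``predict(X) -> Y_hat``.

    ``input_layout`` declares what X is: ``"flat"`` (K x N*B design matrix),
    ``"sequence"`` (K x N x B tensor), or ``"state_space"`` (decoder-specific;
    see KalmanDecoder / NaiveBayesDecoder).
    """

    name: str = "decoder"
    input_layout: str = "flat"
    #: hyperparameter search space: name -> (low, high) or list of choices
    default_search_space: dict[str, Any] = {}

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "Decoder":
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def get_params(self) -> dict[str, Any]:
        """Constructor hyperparameters (anything not ending in '_')."""
        return {
            k: v for k, v in vars(self).items()
            if not k.endswith("_") and not k.startswith("_")
        }

    def clone_with(self, **overrides: Any) -> "Decoder":
        """Fresh unfitted copy with some hyperparameters replaced."""
        params = {**self.get_params(), **overrides}
        return type(self)(**params)

    @staticmethod
    def _as_2d(Y: np.ndarray, n_rows: int) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] == 1 and n_rows != 1:
            Y = Y.T
        return Y


DECODER_REGISTRY: dict[str, type[Decoder]] = {}


def register_decoder(cls: type[Decoder]) -> type[Decoder]:
    DECODER_REGISTRY[cls.name] = cls
    return cls


def get_decoder(name: str, **params: Any) -> Decoder:
    """Instantiate a registered decoder by family name."""
    try:
        cls = DECODER_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown decoder {name!r}; available: {sorted(DECODER_REGISTRY)}"
        ) from None
    return cls(**params)
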