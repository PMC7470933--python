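"""Uniform save/load facade for fitted decoders.

Array-based models (Wiener filter/cascade, Kalman, Naive Bayes, the
in-package networks, the ensemble) are stored as HDF5: hyperparameters as
root attributes, fitted arrays as datasets.  Backend-owned models use the
backend's native serialization embedded in the same file: XGBoost boosters
as their JSON export, scikit-learn SVR objects via pickle bytes.

    save_decoder("model.h5", fitted)
    decoder = load_decoder("model.h5")
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import h5py
import numpy as np

from spikedecode._nn import MLPRegressor, RecurrentRegressor
from spikedecode.data_format import Scaler
from spikedecode.decoders.base import DECODER_REGISTRY, Decoder
from spikedecode.ensemble import EnsembleModel

__all__ = ["save_decoder", "load_decoder"]


def _store(group: h5py.Group, name: str, value) -> None:
    if isinstance(value, np.ndarray):
        group.create_dataset(name, data=value)
    elif isinstance(value, Scaler):
        sub = group.create_group(name)
        sub.attrs["__type__"] = "Scaler"
        sub.attrs["mode"] = value.mode
        if value.mean_ is not None:
            sub.create_dataset("mean", data=value.mean_)
            sub.create_dataset("scale", data=value.scale_)
    elif isinstance(value, (MLPRegressor, RecurrentRegressor)):
        sub = group.create_group(name)
        sub.attrs["__type__"] = type(value).__name__
        sub.attrs["config"] = json.dumps(
            {k: v for k, v in vars(value).items() if not k.endswith("_")})
        arrays = sub.create_group("arrays")
        if isinstance(value, MLPRegressor):
            for i, (W, b) in enumerate(value.hidden_):
                arrays.create_dataset(f"W{i}", data=W)
                arrays.create_dataset(f"b{i}", data=b)
            arrays.create_dataset("Wo", data=value.out_[0])
            arrays.create_dataset("bo", data=value.out_[1])
        else:
            for nm, arr in zip(("Wx", "Wh", "b", "Wo", "bo"), value._params):
                arrays.create_dataset(nm, data=arr)
    elif isinstance(value, list) and value and all(
            isinstance(v, np.ndarray) for v in value):
        sub = group.create_group(name)
        sub.attrs["__type__"] = "array_list"
        for i, arr in enumerate(value):
            sub.create_dataset(f"item_{i:03d}", data=arr)
    elif type(value).__name__ == "XGBRegressor":
        group.create_dataset(
            name, data=np.frombuffer(
                value.get_booster().save_raw("json"), dtype=np.uint8))
        group[name].attrs["__type__"] = "xgboost_json"
    elif isinstance(value, Decoder):
        sub = group.create_group(name)
        sub.attrs["__type__"] = "decoder"
        _write_decoder(sub, value)
    elif isinstance(value, list):
        sub = group.create_group(name)
        sub.attrs["__type__"] = "generic_list"
        for i, v in enumerate(value):
            _store(sub, f"item_{i:03d}", v)
    else:
        # last resort: pickle (scikit-learn estimators land here)
        data = np.frombuffer(pickle.dumps(value), dtype=np.uint8)
        group.create_dataset(name, data=data)
        group[name].attrs["__type__"] = "pickle"


def _restore(node):
    if isinstance(node, h5py.Dataset):
        kind = node.attrs.get("__type__")
        if kind == "pickle":
            return pickle.loads(node[()].tobytes())
        if kind == "xgboost_json":
            from xgboost import XGBRegressor

            model = XGBRegressor()
            import xgboost

            booster = xgboost.Booster()
            booster.load_model(bytearray(node[()].tobytes()))
            model._Booster = booster
            return model
        return node[()]
    kind = node.attrs.get("__type__")
    if kind == "Scaler":
        return Scaler(
            mode=str(node.attrs["mode"]),
            mean_=node["mean"][()] if "mean" in node else None,
            scale_=node["scale"][()] if "scale" in node else None,
        )
    if kind in ("MLPRegressor", "RecurrentRegressor"):
        cfg = json.loads(node.attrs["config"])
        arrays = node["arrays"]
        if kind == "MLPRegressor":
            model = MLPRegressor(**cfg)
            model.hidden_ = []
            i = 0
            while f"W{i}" in arrays:
                model.hidden_.append([arrays[f"W{i}"][()], arrays[f"b{i}"][()]])
                i += 1
            model.out_ = [arrays["Wo"][()], arrays["bo"][()]]
        else:
            model = RecurrentRegressor(**cfg)
            model.Wx_ = arrays["Wx"][()]
            model.Wh_ = arrays["Wh"][()]
            model.b_ = arrays["b"][()]
            model.Wo_ = arrays["Wo"][()]
            model.bo_ = arrays["bo"][()]
        return model
    if kind == "array_list":
        return [node[k][()] for k in sorted(node)]
    if kind == "generic_list":
        return [_restore(node[k]) for k in sorted(node)]
    if kind == "decoder":
        return _read_decoder(node)
    raise ValueError(f"unrecognized serialized node {node.name}")


def _write_decoder(group: h5py.Group, decoder: Decoder) -> None:
    group.attrs["decoder_name"] = decoder.name
    group.attrs["params"] = json.dumps(decoder.get_params(), default=list)
    fitted = group.create_group("fitted")
    for key, value in vars(decoder).items():
        if key.endswith("_") and not key.startswith("_"):
            _store(fitted, key, value)


def _read_decoder(group: h5py.Group) -> Decoder:
    name = str(group.attrs["decoder_name"])
    params = json.loads(group.attrs["params"])
    if name == "ensemble":
        decoder = EnsembleModel(**params)
    else:
        decoder = DECODER_REGISTRY[name](**params)
    for key in group["fitted"]:
        setattr(decoder, key, _restore(group["fitted"][key]))
    return decoder


def save_decoder(path: str | Path, decoder: Decoder) -> None:
    """Write a fitted decoder (any registered family, or the ensemble)."""
    with h5py.File(path, "w") as f:
        _write_decoder(f, decoder)


def load_decoder(path: str | Path) -> Decoder:
    """Reconstruct a fitted decoder saved by :func:`save_decoder`."""
    with h5py.File(path, "r") as f:
        return _read_decoder(f)
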