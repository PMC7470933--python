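"""Run configuration: schema validation and defaults.

A run is fully described by a YAML or JSON file; unknown keys are rejected
so typos fail loudly before any computation, and the resolved configuration
(defaults filled in) is written next to the results for auditability.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from spikedecode.data_format import LagSpec

__all__ = ["RunConfig", "SimulationSpec", "LagConfig", "load_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSpec(_StrictModel):
    """Generate data instead of loading it from files."""

    mode: Literal["cortical", "hippocampal"] = "cortical"
    n_neurons: int = Field(30, gt=0)
    duration: float = Field(600.0, gt=0)


class LagConfig(_StrictModel):
    bins_before: int = Field(0, ge=0)
    bins_current: Literal[0, 1] = 1
    bins_after: int = Field(0, ge=0)

    def to_lagspec(self) -> LagSpec:
        return LagSpec(self.bins_before, self.bins_current, self.bins_after)


class RunConfig(_StrictModel):
    """Everything needed for one reproducible decoding run."""

    # data source: either file paths or a simulation spec
    spikes_path: str | None = None
    outputs_path: str | None = None
    simulate: SimulationSpec | None = None

    bin_size: float = Field(0.05, gt=0)
    lags: LagConfig = LagConfig(bins_before=4, bins_current=1, bins_after=0)
    lag_overrides: dict[str, LagConfig] = {}

    decoders: list[str] = ["wiener_filter"]
    decoder_params: dict[str, dict[str, Any]] = {}
    search_spaces: dict[str, dict[str, Any]] = {}
    ensemble_stacker: Literal["feedforward", "linear"] = "feedforward"

    n_folds: int = Field(10, ge=2)
    budget: int = Field(0, ge=0)
    strategy: Literal["bayesian", "random", "grid"] = "bayesian"
    seed: int = 0
    output_dir: str = "results"

    @field_validator("decoders")
    @classmethod
    def _known_decoders(cls, v: list[str]) -> list[str]:
        from spikedecode.decoders import DECODER_REGISTRY

        known = set(DECODER_REGISTRY) | {"ensemble"}
        bad = [d for d in v if d not in known]
        if bad:
            raise ValueError(f"unknown decoder(s) {bad}; available: {sorted(known)}")
        return v

    def data_source_valid(self) -> None:
        if self.simulate is None and (self.spikes_path is None
                                      or self.outputs_path is None):
            raise ValueError(
                "config must set either 'simulate' or both "
                "'spikes_path' and 'outputs_path'"
            )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    cfg = RunConfig.model_validate(raw)
    cfg.data_source_valid()
    return cfg
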