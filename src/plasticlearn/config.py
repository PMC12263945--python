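"""Run configuration: one validated record per model component plus run
control, loadable from YAML or JSON."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .cognitive_load import LoadParams
from .controller import ControllerParams
from .plasticity import PlasticityParams
from .rewiring import RewireParams
from .stimulus import StimulusSpec

__all__ = ["NetworkConfig", "RunControl", "SimulationConfig", "load_config", "demo_config"]


class NetworkConfig(BaseModel):
    n_neurons: int = 30
    edge_density: float = 0.15
    weight_init_low: float = 0.05
    weight_init_high: float = 0.15
    bias: float = 0.0
    activation_fn: str = "logistic"
    convention: str = "incoming"  # which synapses feed a neuron's drive

    @model_validator(mode="after")
    def _check(self):
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be at least 2")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must lie in [0, 1]")
        if self.weight_init_low > self.weight_init_high:
            raise ValueError("weight_init_low must not exceed weight_init_high")
        if self.convention not in ("incoming", "outgoing"):
            raise ValueError("convention must be 'incoming' or 'outgoing'")
        return self


class RunControl(BaseModel):
    dt: float = 0.05
    n_steps: int = 200
    seed: int = 0
    snapshot_every: int = 50
    intervention_hold_steps: int = 10  # difficulty freeze after a trigger
    rewiring_enabled: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if self.snapshot_every < 1:
            raise ValueError("snapshot_every must be at least 1")
        if self.intervention_hold_steps < 0:
            raise ValueError("intervention_hold_steps must be nonnegative")
        return self


class SimulationConfig(BaseModel):
    network: NetworkConfig = Field(default_factory=NetworkConfig)
    plasticity: PlasticityParams = Field(default_factory=PlasticityParams)
    load: LoadParams = Field(default_factory=LoadParams)
    rewiring: RewireParams = Field(default_factory=RewireParams)
    controller: ControllerParams = Field(default_factory=ControllerParams)
    stimulus: StimulusSpec = Field(default_factory=StimulusSpec)
    run: RunControl = Field(default_factory=RunControl)

    def with_overrides(self, overrides: dict) -> "SimulationConfig":
        """Copy with dotted-path overrides, e.g. {"plasticity.eta0": 0.1}."""
        data = self.model_dump()
        for key, value in overrides.items():
            section, _, name = key.partition(".")
            if not name or section not in data:
                raise KeyError(f"unknown config field {key!r}")
            if name not in data[section]:
                raise KeyError(f"unknown config field {key!r}")
            data[section][name] = value
        return SimulationConfig.model_validate(data)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML or JSON configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if data is None:
        data = {}
    return SimulationConfig.model_validate(data)


def demo_config(seed: int = 0) -> SimulationConfig:
    """The packaged 200-step closed-loop example configuration."""
    cfg = SimulationConfig()
    cfg = cfg.model_copy(deep=True)
    cfg.run.seed = seed
    cfg.rewiring.E_max = 4 * cfg.network.n_neurons
    return cfg


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.model_dump(), indent=2) + "\n")
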