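"""Run configuration: nested dataclasses loadable from YAML/JSON."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .bpnn import TrainConfig
from .control import ControllerGains, PlantParams
from .features import WindowSpec
from .preprocess import FilterSpec
from .synth import SynthConfig


def _build(cls, d: dict | None):
    """Instantiate a config dataclass from a plain dict, rejecting unknown keys."""
    d = dict(d or {})
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for f in fields(cls):
        if f.name in d and isinstance(d[f.name], list):
            d[f.name] = tuple(d[f.name])
    return cls(**d)


@dataclass
class RunConfig:
    data_dir: str = "data"
    out_dir: str = "out"
    model_file: str = "model.json"
    n_trials: int = 5
    accept_threshold: float = 0.90
    synth: SynthConfig = field(default_factory=SynthConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    window: WindowSpec = field(default_factory=WindowSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    plant: PlantParams = field(default_factory=PlantParams)
    gains: ControllerGains = field(default_factory=ControllerGains)

    def with_seed(self, seed: int) -> "RunConfig":
        """Return a copy with every stochastic stage reseeded from ``seed``."""
        cfg = load_run_config_dict(self.to_dict())
        cfg.synth.seed = seed
        cfg.train.seed = seed
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def load_run_config_dict(d: dict) -> RunConfig:
    d = dict(d or {})
    nested = {
        "synth": SynthConfig, "filter": FilterSpec, "window": WindowSpec,
        "train": TrainConfig, "plant": PlantParams, "gains": ControllerGains,
    }
    kwargs = {}
    for key, cls in nested.items():
        sub = d.pop(key, None)
        kwargs[key] = _build(cls, sub) if not isinstance(sub, cls) else sub
    top = {f.name for f in fields(RunConfig)} - set(nested)
    unknown = set(d) - top
    if unknown:
        raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
    kwargs.update(d)
    return RunConfig(**kwargs)


def load_config(path=None) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON) file; defaults when path is None."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    return load_run_config_dict(yaml.safe_load(text) or {})
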