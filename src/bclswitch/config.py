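"""Run configuration: YAML file with defaults, exhaustive validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import yaml

from .network import default_rate_params

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """All schema violations, reported together."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass
class SweepBlock:
    param: str = "kptBid"
    decades: float = 3.0
    points: int = 60
    gap_factor: float = 5.0


@dataclass
class MonteCarloBlock:
    n_iterations: int = 10000
    q_low: float = 0.1
    q_high: float = 10.0
    sampling: str = "log"
    seed: int = 1


@dataclass
class MutateBlock:
    n_models: int = 10
    n_mutations: int = 5
    n_iterations: int = 1000
    seed: int = 7


@dataclass
class RunConfig:
    network: str = "default"  # "default" or a path to a network YAML
    overrides: dict[str, float] = field(default_factory=dict)
    sweep: SweepBlock = field(default_factory=SweepBlock)
    montecarlo: MonteCarloBlock = field(default_factory=MonteCarloBlock)
    mutate: MutateBlock = field(default_factory=MutateBlock)
    output_dir: str = "."

    def to_dict(self) -> dict:
        return asdict(self)


_BLOCKS = {"sweep": SweepBlock, "montecarlo": MonteCarloBlock, "mutate": MutateBlock}


def _build_block(cls, doc: Mapping[str, Any], prefix: str, errors: list[str]):
    block = cls()
    known = set(block.__dataclass_fields__)
    for key, value in doc.items():
        if key not in known:
            errors.append(f"unknown key {prefix}.{key}")
            continue
        setattr(block, key, value)
    return block


def validate_config(doc: Mapping[str, Any]) -> RunConfig:
    errors: list[str] = []
    cfg = RunConfig()
    known_top = {"network", "overrides", "output_dir", *_BLOCKS}
    for key in doc:
        if key not in known_top:
            errors.append(f"unknown key {key}")
    if "network" in doc:
        cfg.network = str(doc["network"])
    if "output_dir" in doc:
        cfg.output_dir = str(doc["output_dir"])
    params = default_rate_params()
    for name, value in (doc.get("overrides") or {}).items():
        if name not in params:
            errors.append(f"override names unknown parameter {name!r}")
        elif not isinstance(value, (int, float)) or value < 0:
            errors.append(f"override {name!r} must be a nonnegative number")
        else:
            cfg.overrides[name] = float(value)
    for block_name, cls in _BLOCKS.items():
        if block_name in doc:
            block_doc = doc[block_name] or {}
            if not isinstance(block_doc, Mapping):
                errors.append(f"{block_name} must be a mapping")
                continue
            setattr(cfg, block_name, _build_block(cls, block_doc, block_name, errors))
    mc = cfg.montecarlo
    if mc.sampling not in ("log", "linear"):
        errors.append("montecarlo.sampling must be 'log' or 'linear'")
    if not (0 < mc.q_low <= mc.q_high):
        errors.append("montecarlo q interval must satisfy 0 < q_low <= q_high")
    if mc.n_iterations < 1:
        errors.append("montecarlo.n_iterations must be >= 1")
    if cfg.sweep.points < 2:
        errors.append("sweep.points must be >= 2")
    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path, "r") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, Mapping):
        raise ConfigError(["configuration must be a mapping"])
    return validate_config(doc)
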