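"""Structured run configuration for the command-line drivers.

A run config is a YAML (or JSON) mapping with nested blocks; unknown keys
are rejected before any computation starts so typos fail fast.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .network import LITRConfig

__all__ = ["SimulationBlock", "ScanBlock", "RunConfig", "load_config"]


class ConfigError(ValueError):
    pass


def _from_mapping(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}; "
                          f"allowed: {sorted(allowed)}")
    return cls(**data)


@dataclass(frozen=True)
class SimulationBlock:
    t_end: float = 1e5
    sample_dt: float = 1.0
    seed: int = 0
    burn_in_frac: float = 0.01
    excess: int = 400

    def __post_init__(self):
        if self.t_end <= 0 or self.sample_dt <= 0:
            raise ConfigError("t_end and sample_dt must be positive")
        if not 0 <= self.burn_in_frac < 1:
            raise ConfigError("burn_in_frac must be in [0, 1)")


@dataclass(frozen=True)
class ScanBlock:
    axis1: str = "iptg_nM"
    axis2: str = "dox_nM"
    start1: float = 1e2
    stop1: float = 1e5
    n1: int = 4
    start2: float = 1.0
    stop2: float = 1e3
    n2: int = 4
    log: bool = True

    def values(self):
        import numpy as np
        fn = np.geomspace if self.log else np.linspace
        return fn(self.start1, self.stop1, self.n1), \
            fn(self.start2, self.stop2, self.n2)


@dataclass(frozen=True)
class RunConfig:
    model: str = "litr"                   # reduced | generic | litr
    n_lacI: int = 1
    n_tetR: int = 1
    iptg: float = 0.0
    dox: float = 0.0
    volume: float = 1.0
    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    scan: ScanBlock = field(default_factory=ScanBlock)
    output_dir: str = "."

    def __post_init__(self):
        if self.model not in ("reduced", "generic", "litr"):
            raise ConfigError(f"unknown model {self.model!r}")

    def litr_config(self) -> LITRConfig:
        return LITRConfig(n_lacI=self.n_lacI, n_tetR=self.n_tetR,
                          iptg=self.iptg, dox=self.dox, volume=self.volume)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load and validate a config file, applying flat CLI overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
    if overrides:
        for key, value in overrides.items():
            if value is None:
                continue
            if key in ("t_end", "sample_dt", "seed", "burn_in_frac", "excess"):
                data.setdefault("simulation", {})[key] = value
            else:
                data[key] = value
    sim = _from_mapping(SimulationBlock, data.pop("simulation", {}),
                        "simulation block")
    scan = _from_mapping(ScanBlock, data.pop("scan", {}), "scan block")
    cfg = _from_mapping(RunConfig, {**data, "simulation": sim, "scan": scan},
                        "run config")
    return cfg
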