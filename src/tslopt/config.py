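"""Run configuration: validated, serializable, and filled with study defaults.

An empty config is a complete, runnable configuration: the defaults are the
study conditions (constraint-box parameter ranges, the non-uniform TSL
grid, the per-model criterion weights, SNR 30, 500 scoring draws, 2000
Monte Carlo replicates). Every run is regenerable from its config plus the
recorded seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

log = logging.getLogger(__name__)

from .crlb import DEFAULT_WEIGHTS
from .exceptions import ConfigError

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

_VALID_MODELS = ("mono", "bi", "stretched")
_VALID_CRITERIA = ("crlb", "mcrlb")
_VALID_GRIDS = ("paper", "fine")
_VALID_METHODS = ("poss", "exhaustive")


@dataclass
class RunConfig:
    """Everything needed to reproduce an optimization / simulation run."""

    model: str = "bi"
    criterion: str = "crlb"
    grid: str = "paper"
    k: int = 6
    weights: list | None = None  # None -> per-model default
    s: int = 500  # parameter draws for schedule scoring
    snr: float = 30.0
    replicates: int = 2000
    seed: int = 0
    n_starts: int = 5
    method: str = "poss"
    poss_iterations: int = 200_000
    output: str | None = None

    def __post_init__(self):
        if self.model not in _VALID_MODELS:
            raise ConfigError(f"model must be one of {_VALID_MODELS}, got {self.model!r}")
        if self.criterion not in _VALID_CRITERIA:
            raise ConfigError(f"criterion must be one of {_VALID_CRITERIA}, got {self.criterion!r}")
        if self.grid not in _VALID_GRIDS:
            raise ConfigError(f"grid must be one of {_VALID_GRIDS}, got {self.grid!r}")
        if self.method not in _VALID_METHODS:
            raise ConfigError(f"method must be one of {_VALID_METHODS}, got {self.method!r}")
        for name in ("k", "s", "replicates", "n_starts", "poss_iterations"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.snr <= 0:
            raise ConfigError(f"snr must be positive, got {self.snr}")
        if self.seed < 0:
            raise ConfigError(f"seed must be non-negative, got {self.seed}")
        if self.weights is None:
            self.weights = list(DEFAULT_WEIGHTS[self.model])
        w = [float(x) for x in self.weights]
        if len(w) != len(DEFAULT_WEIGHTS[self.model]):
            raise ConfigError(
                f"weights must have {len(DEFAULT_WEIGHTS[self.model])} entries for model {self.model!r}"
            )
        if any(x < 0 for x in w):
            raise ConfigError("weights must be non-negative")
        self.weights = w

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Read a YAML/JSON config file; unknown keys are an error naming the field."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    cfg = RunConfig(**data)
    for name in sorted(known - set(data)):
        log.debug("config field %r defaulted to %r (study default)", name, getattr(cfg, name))
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    else:
        path.write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of a config, embedded in written reports."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
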