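"""Run configuration: one structured file driving generate -> train -> evaluate.

Defaults are the study conditions (F=15, sigma=0.15, 30 repetitions, 5
attention heads, learning rate 0.001, batch 128, patience 10, 500 epochs).
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    grammar: str = ""
    F: int = 15
    sigma: float = 0.15
    repetitions: int = 30
    seed: int = 1
    n_heads: int = 5
    positional_encoding: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 128
    patience: int = 10
    max_epochs: int = 500
    balance: bool = True
    prototype_spread: float = 1.0
    min_distance_factor: float | None = None
    output_dir: str = "runs"

    def validate(self) -> "RunConfig":
        if not self.grammar:
            raise ValueError("config field 'grammar' (path to a grammar file) is required")
        if self.F < 1:
            raise ValueError(f"config field 'F' must be >= 1, got {self.F}")
        if self.sigma < 0:
            raise ValueError(f"config field 'sigma' must be >= 0, got {self.sigma}")
        if self.repetitions < 1:
            raise ValueError(f"config field 'repetitions' must be >= 1, got {self.repetitions}")
        if self.learning_rate <= 0:
            raise ValueError("config field 'learning_rate' must be positive")
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValueError("batch_size, patience and max_epochs must be >= 1")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) if path.suffix != ".json" else json.loads(
        path.read_text()
    )
    if raw is None:
        raw = {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; known keys: {sorted(known)}")
    return RunConfig(**raw).validate()


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
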