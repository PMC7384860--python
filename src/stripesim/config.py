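"""Run configuration files (YAML/JSON, strict schema).

Unknown keys are rejected so that a mistyped parameter override in a sweep
fails loudly instead of being silently ignored.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import Params

__all__ = ["RunConfig"]

_FIELDS = {"genotype", "seed", "param_overrides", "end_sl",
           "checkpoint_stages", "out_dir", "metrics", "render"}


@dataclass
class RunConfig:
    genotype: str = "WT"
    seed: int = 0
    param_overrides: dict = field(default_factory=dict)
    end_sl: float | None = None
    checkpoint_stages: tuple = ("PR", "SP", "SA", "J")
    out_dir: str | None = None
    metrics: bool = True
    render: bool = False

    def __post_init__(self):
        valid = {f.name for f in dataclasses.fields(Params)}
        unknown = set(self.param_overrides) - valid
        if unknown:
            raise ValueError(f"unknown parameter overrides: {sorted(unknown)}")
        self.checkpoint_stages = tuple(self.checkpoint_stages)

    def params(self, base: Params | None = None) -> Params:
        return (base or Params()).replace(**self.param_overrides)

    # --- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["checkpoint_stages"] = list(self.checkpoint_stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> Path:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=1)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)
        return path

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
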