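"""Flat run configuration with validated defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    min_score: int = 700
    cutoff: float = 1.5
    prevalence: float = 0.75
    max_nodes: int = 7
    max_r_layers: int = 2
    max_k_layers: int = 5
    quantile: float = 0.75
    min_tfs: int = 5
    reps: int = 10
    seed: int = 0

    _RANGES = {
        "min_score": (1, 999),
        "cutoff": (0.0, float("inf")),
        "prevalence": (1e-9, 1.0),
        "max_nodes": (3, 50),
        "max_r_layers": (1, 10),
        "max_k_layers": (1, 20),
        "quantile": (1e-9, 1.0 - 1e-9),
        "min_tfs": (1, 10**6),
        "reps": (1, 10**6),
        "seed": (0, 2**63 - 1),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValueError(f"config parameter {name}={value} outside [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "RunConfig":
        allowed = {f.name for f in fields(cls)}
        unknown = set(mapping) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def read(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"config file {path} must hold a flat key-value mapping")
        return cls.from_dict(payload)

    def merged(self, **overrides) -> "RunConfig":
        """New config with non-None overrides applied (flags win)."""
        data = self.to_dict()
        data.update({k: v for k, v in overrides.items() if v is not None})
        return self.from_dict(data)
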