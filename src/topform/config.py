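"""Run configuration shared by the command-line stages.

A single flat YAML file (key: value) holds the tolerances and defaults; CLI
flags override individual keys.  The file round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    """Pipeline-level parameters.

    tolerance_da: Da window for Δm-to-modification matching (default 0.5).
    ppm: fragment matching tolerance (default 15 ppm).
    fdr: PrSM-level target-decoy q threshold (default 0.01).
    bin / range: Δm histogram bin width (Da) and window.
    """

    tolerance_da: float = 0.5
    ppm: float = 15.0
    fdr: float = 0.01
    bin: float = 1.0
    range: tuple[float, float] = (-500.0, 500.0)
    seed: int = 0

    def validate(self) -> None:
        for name in ("tolerance_da", "ppm", "bin"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.fdr < 1:
            raise ConfigError(f"fdr must be in (0,1), got {self.fdr}")
        if self.range[0] >= self.range[1]:
            raise ConfigError(f"empty histogram range {self.range}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["range"] = list(self.range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "range" in data:
            data = dict(data, range=tuple(data["range"]))
        cfg = cls(**data)
        cfg.validate()
        return cfg


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a key: value mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8"
    )
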