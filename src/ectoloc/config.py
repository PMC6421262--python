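"""Scenario configuration (YAML/JSON) for the simulation CLI."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .geometry import RegionSpec

__all__ = ["HeartConfig", "TorsoConfig", "ScenarioConfig"]


@dataclass
class HeartConfig:
    n_subdiv: int = 3
    long_axis: float = 90.0  # mm
    short_axis: float = 50.0  # mm
    wall_thickness: float = 10.0  # mm
    seed: int = 0
    jitter: float = 0.1


@dataclass
class TorsoConfig:
    n_electrodes: int = 240
    standoff: float = 40.0  # mm
    seed: int = 0


@dataclass
class ScenarioConfig:
    """Complete description of one forward-simulation scenario."""

    heart: HeartConfig = field(default_factory=HeartConfig)
    torso: TorsoConfig = field(default_factory=TorsoConfig)
    cv_global: float = 0.8  # m/s
    transmural_factor: float = 0.5
    regions: list[RegionSpec] = field(default_factory=list)
    focus: int = 0
    dt: float = 1.0  # ms
    span: float | None = None  # ms; default: activation duration rounded up

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        heart = HeartConfig(**d.pop("heart", {}))
        torso = TorsoConfig(**d.pop("torso", {}))
        regions = [RegionSpec(**r) for r in d.pop("regions", [])]
        return cls(heart=heart, torso=torso, regions=regions, **d)

    @classmethod
    def load(cls, path) -> "ScenarioConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path) -> None:
        d = asdict(self)
        text = (json.dumps(d, indent=1) if str(path).endswith(".json")
                else yaml.safe_dump(d, sort_keys=False))
        Path(path).write_text(text)
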