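"""Run configuration: a serializable description of one full analysis run.

A :class:`RunConfig` captures every tunable setting of the pipeline -
cohort/generator parameters, preprocessing, detection windows, audiometry
criterion, binaural windows, statistics options and the master seed - so a
run is fully reproducible from (config, seed) alone.  YAML round-trips are
canonical (sorted keys), so serialize(parse(x)) == serialize(x).
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .core import ITD_GRID_MS


def _default_sections() -> dict:
    return {
        "synth": {
            "n_per_group": 2,
            "design": None,  # null -> full sex x genotype factorial
            "n_epochs": 50,
            "level_db": 90.0,
            "itds_ms": list(ITD_GRID_MS),
            "audiogram_levels_db": list(range(90, 15, -10)),
            "include": ["monaural", "binaural", "audiogram"],
            "effects": "study",  # 'study' | 'null'
            "noise": {
                "background_sd_av": 0.3,
                "artifact_rate": 0.05,
                "artifact_amplitude_av": 15.0,
            },
        },
        "preprocess": {
            "rejection_threshold_av": None,  # null -> robust default
            "filter_low_hz": 50.0,
            "filter_high_hz": 3000.0,
            "filter_order": 2,
        },
        "peaks": {
            "windows_ms": None,  # null -> defaults from the response model
            "min_prominence_av": 0.1,
            "post_window_ms": 1.5,
        },
        "audiogram": {
            "criterion_multiple": 2.0,
            "response_window_ms": [0.5, 9.0],
        },
        "binaural": {
            "half_window_ms": 1.5,
            "floor_multiple": 3.0,
        },
        "stats": {
            "enabled": True,
            "fixed": "sex * genotype * condition + litter",
            "adjust": "tukey",
        },
        "seed": 0,
    }


@dataclass
class RunConfig:
    """Nested-mapping configuration with canonical YAML serialization."""

    sections: dict = field(default_factory=_default_sections)

    def __post_init__(self) -> None:
        base = _default_sections()
        merged = _deep_merge(base, self.sections)
        unknown = set(self.sections) - set(base)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        self.sections = merged

    def __getitem__(self, key: str):
        return self.sections[key]

    @property
    def seed(self) -> int:
        return int(self.sections["seed"])

    def with_seed(self, seed: int) -> "RunConfig":
        s = copy.deepcopy(self.sections)
        s["seed"] = int(seed)
        return RunConfig(s)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.sections, sort_keys=True,
                              default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ValueError("config YAML must be a mapping")
        return cls(dict(data))

    @classmethod
    def load(cls, path: Optional[Path]) -> "RunConfig":
        if path is None:
            return cls()
        return cls.from_yaml(Path(path).read_text(encoding="utf-8"))

    def save(self, path: Path) -> None:
        Path(path).write_text(self.to_yaml(), encoding="utf-8")


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if k in out and isinstance(out[k], dict) and isinstance(v, Mapping):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out
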