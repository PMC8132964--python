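"""Run configuration: YAML round-trip of every tunable parameter."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .detector import DeltaPointConfig
from .preprocess import DEFAULT_QUALITY_THRESHOLD, DEFAULT_QUALITY_WEIGHTS
from .simulate import SubjectParams, UCOProtocol, make_protocol

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    protocol: UCOProtocol = field(default_factory=make_protocol)
    subject: SubjectParams = field(default_factory=SubjectParams)
    detector: DeltaPointConfig = field(default_factory=DeltaPointConfig)
    quality_weights: tuple[float, float, float] = DEFAULT_QUALITY_WEIGHTS
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
    late_limit_min: float = 2.0
    early_limit_min: float = 25.0
    cohort_size: int = 14
    master_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["quality_weights"] = list(self.quality_weights)
        for key in ("protocol", "subject", "detector"):
            for k, v in d[key].items():
                if isinstance(v, tuple):
                    d[key][k] = list(v)
        return d


_SECTION_TYPES = {
    "protocol": UCOProtocol,
    "subject": SubjectParams,
    "detector": DeltaPointConfig,
}


def _build_section(cls, data: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {', '.join(sorted(unknown))}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config; unknown keys raise a ValueError naming the key."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    valid_top = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - valid_top
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
    kwargs = {}
    for key, val in raw.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], val or {})
        elif key == "quality_weights":
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


def save_config(path: str | Path, config: RunConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
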