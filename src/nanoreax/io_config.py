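"""YAML campaign configuration: a flat, validated mapping onto the module
config dataclasses.

Unknown keys are rejected up front (before any computation) so typos fail
fast; every omitted key keeps its library default.
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .active_learning import ALConfig
from .builders import BuilderPolicy
from .ensemble import SelectionThresholds, TrainConfig
from .md import MDParams
from .schedules import SchedulePolicy


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "builder_policy": BuilderPolicy,
    "schedule_policy": SchedulePolicy,
    "md_params": MDParams,
    "train_config": TrainConfig,
    "thresholds": SelectionThresholds,
}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown keys in {section}: {sorted(unknown)}; valid: {sorted(valid)}"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def load_al_config(path) -> ALConfig:
    """Load and validate a campaign configuration from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    top_valid = {f.name for f in fields(ALConfig)}
    unknown = set(raw) - top_valid
    if unknown:
        raise ConfigError(
            f"unknown top-level keys: {sorted(unknown)}; valid: {sorted(top_valid)}"
        )
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"{key} must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        elif key == "bootstrap_separation_range":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return ALConfig(**kwargs)
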