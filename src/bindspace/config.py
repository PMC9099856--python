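"""Pipeline configuration: one INI section per module, strict keys.

Every default is the module default; unknown sections or keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import configparser
import dataclasses
import os

from .dg import DGParams
from .ec import ECParams
from .ensemble import DEFAULT_CLUSTER_THRESHOLD, DEFAULT_MAX_POSES, DEFAULT_ORIENTATION_ANGLE
from .interactions import InteractionCriteria
from .mc import EnergyModel, MCConfig


class ConfigError(ValueError):
    """Unknown key/section or unparsable value in a config file."""


@dataclasses.dataclass
class EnsembleOptions:
    max_poses: int = DEFAULT_MAX_POSES
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD
    orientation_max_angle: float = DEFAULT_ORIENTATION_ANGLE
    score_key: str = "dG"
    state_key: str = "state"


@dataclasses.dataclass
class StatsOptions:
    transform: str = "log10"  # log10 | identity


@dataclasses.dataclass
class SimulateOptions:
    n_poses: int = 100
    seed: int = 0


@dataclasses.dataclass
class PipelineConfig:
    interactions: InteractionCriteria = dataclasses.field(default_factory=InteractionCriteria)
    ensemble: EnsembleOptions = dataclasses.field(default_factory=EnsembleOptions)
    mc: MCConfig = dataclasses.field(default_factory=MCConfig)
    ec: ECParams = dataclasses.field(default_factory=ECParams)
    dg: DGParams = dataclasses.field(default_factory=DGParams)
    stats: StatsOptions = dataclasses.field(default_factory=StatsOptions)
    simulate: SimulateOptions = dataclasses.field(default_factory=SimulateOptions)
    energy: EnergyModel = dataclasses.field(default_factory=EnergyModel)

    def as_dict(self) -> dict:
        """Flat parameter record for output sidecars."""
        out: dict[str, dict] = {}
        for f in dataclasses.fields(self):
            section = getattr(self, f.name)
            out[f.name] = {
                sf.name: _jsonable(getattr(section, sf.name))
                for sf in dataclasses.fields(section)
            }
        return out


def _jsonable(v):
    if isinstance(v, (int, float, str, bool)) or v is None:
        return v
    if isinstance(v, dict):
        return {str(k): _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return str(v)


_SKIP_KEYS = {("mc", "monitored_pairs"), ("energy", "lj_params")}


def load_config(path: str | os.PathLike | None) -> PipelineConfig:
    """Read an INI config; missing file path of None means all defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    if not os.path.exists(path):
        raise ConfigError(f"no such config file: {path}")
    parser = configparser.ConfigParser()
    parser.read(os.fspath(path))
    sections = {f.name: f for f in dataclasses.fields(cfg)}
    for section in parser.sections():
        if section not in sections:
            raise ConfigError(f"unknown config section [{section}]")
        target = getattr(cfg, section)
        fields = {f.name: f for f in dataclasses.fields(target)}
        updates = {}
        for key, raw in parser.items(section):
            if key not in fields or (section, key) in _SKIP_KEYS:
                raise ConfigError(f"unknown key {key!r} in section [{section}]")
            updates[key] = _coerce(raw, getattr(target, key), section, key)
        if updates:
            if dataclasses.fields(target) and getattr(type(target), "__dataclass_params__").frozen:
                setattr(cfg, section, dataclasses.replace(target, **updates))
            else:
                for k, v in updates.items():
                    setattr(target, k, v)
    return cfg


def _coerce(raw: str, current, section: str, key: str):
    try:
        if isinstance(current, bool):
            if raw.lower() in ("1", "true", "yes", "on"):
                return True
            if raw.lower() in ("0", "false", "no", "off"):
                return False
            raise ValueError(raw)
        if isinstance(current, int):
            return int(raw)
        if isinstance(current, float):
            return float(raw)
        if isinstance(current, str):
            return raw
    except ValueError as exc:
        raise ConfigError(f"cannot parse [{section}] {key} = {raw!r}") from exc
    raise ConfigError(f"key {key!r} in [{section}] is not settable from a config file")
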