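"""Run configuration: YAML parsing, validation and defaults.

An empty configuration file is a complete, runnable configuration: every
default is the Falmouth-bay case study (container transfer coefficients,
behavioural limits 0.1/0.27 m/s, DO values 8.98/6.4/4.5 mg/L, consumption
5e-5 mg/s, 97.6 m array) applied to the default synthetic tide.  Unknown
keys are rejected with an error naming the key, so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .do_budget import DOBudget
from .rearing_eval import Scenario
from .synthetic import SyntheticSpec
from .transfer import TransferCoefficients


class ConfigError(ValueError):
    """Configuration schema violation; the message names the offending key."""


def parse_coverage(value) -> float:
    """Normalise a biofouling coverage to a fraction in [0, 1].

    Accepts fractions (0.33), percentages as numbers > 1 (33) or strings
    with a percent sign ("33%").
    """
    if isinstance(value, str):
        v = value.strip()
        if v.endswith("%"):
            return float(v[:-1]) / 100.0
        value = float(v)
    value = float(value)
    if value > 1.0:
        value = value / 100.0
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"coverage {value!r} not interpretable as a fraction in [0, 1]")
    return value


@dataclass
class EVPConfig:
    source: str = "synthetic"  # "synthetic" or "file"
    path: str | None = None
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)


@dataclass
class WaveConfig:
    """Optional storm orbital-velocity envelope added to the external field."""

    enabled: bool = False
    H: float = 3.99
    T: float = 7.4
    formula: str = "printed"


@dataclass
class LimitsConfig:
    forage: float = 0.1  # m/s
    mobility: float = 0.27  # m/s
    do_survival: float = 4.5  # mg/L
    do_optimal: float = 6.4  # mg/L


@dataclass
class ScenarioGrid:
    coverages: list = field(default_factory=lambda: [0.0, 0.33, 0.66])
    turbulence: list = field(default_factory=lambda: [False, True])

    def to_scenarios(self) -> list[Scenario]:
        return [
            Scenario(coverage=parse_coverage(c), turbulence=bool(t))
            for c in self.coverages
            for t in self.turbulence
        ]


@dataclass
class OutputConfig:
    directory: str = "report"
    plots: bool = False


@dataclass
class RunConfig:
    evp: EVPConfig = field(default_factory=EVPConfig)
    wave: WaveConfig = field(default_factory=WaveConfig)
    coefficients: TransferCoefficients = field(default_factory=TransferCoefficients)
    do_budget: DOBudget = field(default_factory=DOBudget)
    limits: LimitsConfig = field(default_factory=LimitsConfig)
    scenarios: ScenarioGrid = field(default_factory=ScenarioGrid)
    output: OutputConfig = field(default_factory=OutputConfig)
    seed: int = 42


_NESTED: dict[type, dict[str, type]] = {
    RunConfig: {
        "evp": EVPConfig,
        "wave": WaveConfig,
        "coefficients": TransferCoefficients,
        "do_budget": DOBudget,
        "limits": LimitsConfig,
        "scenarios": ScenarioGrid,
        "output": OutputConfig,
    },
    EVPConfig: {"synthetic": SyntheticSpec},
}


def _build(cls: type, data: Mapping[str, Any], path: str) -> Any:
    if not isinstance(data, Mapping):
        raise ConfigError(f"section {path or 'top level'} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        key = sorted(unknown)[0]
        where = f" in section '{path}'" if path else ""
        raise ConfigError(f"unknown configuration key '{key}'{where}")
    nested = _NESTED.get(cls, {})
    kwargs: dict[str, Any] = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name in nested:
            value = _build(nested[f.name], value or {}, f"{path}.{f.name}" if path else f.name)
        kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{path or 'top level'}': {exc}") from exc


def parse_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration, filling defaults.

    The top-level ``seed`` governs all randomness; it is propagated to the
    synthetic generator unless the file pins ``evp.synthetic.seed``
    explicitly.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    cfg = _build(RunConfig, raw, "")
    synth_raw = (raw.get("evp") or {}).get("synthetic") or {}
    if "seed" not in synth_raw:
        cfg.evp.synthetic.seed = cfg.seed
    return cfg


def _plain(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def dump_config(cfg: RunConfig) -> dict:
    """Configuration as a plain dict that :func:`parse_config` round-trips."""
    return _plain(cfg)


def dump_config_yaml(cfg: RunConfig) -> str:
    return yaml.safe_dump(dump_config(cfg), sort_keys=True)
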