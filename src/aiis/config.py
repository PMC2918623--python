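"""Configuration loading/validation and result writers.

A run configuration is a YAML or JSON document with optional blocks
``patient``, ``sensor``, ``controller``, ``insulin_pump``, ``glucose_pump``,
``engine`` and ``scenario`` plus top-level ``seed`` and ``output_dir``.
Missing blocks/keys take the documented defaults; unknown keys are rejected
with the offending key named.  Outputs are RFC-4180 CSV for tabular data and
JSON for the config snapshot.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .engine import Scenario, SimulationResult, build_scenario
from .params import (BolusInsulinModel, ConfigError, ControllerParams,
                     EngineParams, GLUCOSE_PUMP_DEFAULTS,
                     INSULIN_PUMP_DEFAULTS, PatientParams, PumpSpec,
                     SensorParams, from_mapping)
from .patient import ChallengeEvent

_BLOCKS = {
    "patient": PatientParams,
    "bolus_model": BolusInsulinModel,
    "sensor": SensorParams,
    "controller": ControllerParams,
    "insulin_pump": PumpSpec,
    "glucose_pump": PumpSpec,
    "engine": EngineParams,
}
_TOP_KEYS = set(_BLOCKS) | {"scenario", "seed", "output_dir"}


@dataclass
class RunConfig:
    patient: PatientParams = field(default_factory=PatientParams)
    bolus_model: BolusInsulinModel = field(default_factory=BolusInsulinModel)
    sensor: SensorParams = field(default_factory=SensorParams)
    controller: ControllerParams = field(default_factory=ControllerParams)
    insulin_pump: PumpSpec = field(default_factory=lambda: PumpSpec(
        **asdict(INSULIN_PUMP_DEFAULTS)))
    glucose_pump: PumpSpec = field(default_factory=lambda: PumpSpec(
        **asdict(GLUCOSE_PUMP_DEFAULTS)))
    engine: EngineParams = field(default_factory=EngineParams)
    scenario: Scenario | None = None
    seed: int = 0
    output_dir: str = "aiis-out"

    def to_dict(self) -> dict:
        d = {name: asdict(getattr(self, name)) for name in _BLOCKS}
        d["seed"] = self.seed
        d["output_dir"] = self.output_dir
        if self.scenario is not None:
            d["scenario"] = {
                "duration": self.scenario.duration,
                "challenge_time": self.scenario.challenge_time,
                "events": [{"kind": e.kind, "t_start": e.t_start,
                            "amount": e.amount, "duration": e.duration}
                           for e in self.scenario.events],
            }
        return d


def _parse_scenario(data: dict) -> Scenario:
    if not isinstance(data, dict):
        raise ConfigError("'scenario' block must be a mapping")
    if "kind" in data:
        extra = set(data) - {"kind", "duration", "challenge_time"}
        if extra:
            raise ConfigError(f"unknown key(s) in 'scenario': {sorted(extra)}")
        ep = EngineParams(duration=data.get("duration", 1440.0),
                          challenge_time=data.get("challenge_time", 600.0))
        return build_scenario(data["kind"], ep)
    extra = set(data) - {"events", "duration", "challenge_time"}
    if extra:
        raise ConfigError(f"unknown key(s) in 'scenario': {sorted(extra)}")
    events = [ChallengeEvent(**ev) for ev in data.get("events", [])]
    return Scenario(events=events, duration=data.get("duration", 1440.0),
                    challenge_time=data.get("challenge_time", 600.0))


def parse_config(data: dict | None) -> RunConfig:
    """Validate a config mapping; missing entries take defaults."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}; "
                          f"allowed: {sorted(_TOP_KEYS)}")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        if name in data:
            kwargs[name] = from_mapping(cls, data[name] or {}, name)
    if "scenario" in data and data["scenario"] is not None:
        kwargs["scenario"] = _parse_scenario(data["scenario"])
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "output_dir" in data:
        kwargs["output_dir"] = str(data["output_dir"])
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    return parse_config(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully-defaulted config back out (YAML by extension)."""
    path = Path(path)
    d = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, default=list))
    else:
        path.write_text(yaml.safe_dump(json.loads(
            json.dumps(d, default=list)), sort_keys=False))


def write_outputs(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write timeseries.csv, metrics.csv and config.json into out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    ts_path = out / "timeseries.csv"
    result.to_frame().to_csv(ts_path, index=False)
    paths["timeseries"] = ts_path
    if result.metrics is not None:
        m = result.metrics
        row = {
            "overshoot_peak": m.overshoot_peak,
            "overshoot_duration": m.overshoot_duration,
            "overshoot": m.had_overshoot,
            "undershoot_peak": m.undershoot_peak,
            "undershoot_duration": m.undershoot_duration,
            "undershoot": m.had_undershoot,
            "Ts": m.settling_time,
            "Ts_first": m.settling_time_first,
        }
        mp = out / "metrics.csv"
        pd.DataFrame([row]).to_csv(mp, index=False)
        paths["metrics"] = mp
    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps(
        {"config": result.config, "seed": result.seed}, indent=2, default=list))
    paths["config"] = cfg_path
    return paths


__all__ = ["RunConfig", "parse_config", "load_config", "dump_config",
           "write_outputs", "ConfigError"]
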