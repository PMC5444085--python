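"""Strict schema validation for YAML/JSON configuration files.

Unknown keys are rejected rather than ignored, and every error names the
path of the offending key, so a typo in a scenario file fails loudly
instead of silently running a different scenario.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import yaml

from vectorcycle.errors import ConfigError
from vectorcycle.feeding_cycle import BehaviourProfile, Intervention
from vectorcycle.synthetic import SynthConfig

PROFILE_KEYS = {f.name for f in dataclasses.fields(BehaviourProfile)}
INTERVENTION_KEYS = {"kind", "coverage", "pre_kill", "block", "post_kill", "targets"}
SYNTH_KEYS = {f.name for f in dataclasses.fields(SynthConfig)}
SCENARIO_KEYS = {"profile", "interventions"}


def load_document(path: str | Path) -> Any:
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        if path.suffix.lower() == ".json":
            return json.loads(text)
        return yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc


def _require_mapping(obj: Any, where: str) -> dict:
    if not isinstance(obj, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(obj).__name__}")
    return obj


def _reject_unknown(obj: dict, allowed: set[str], where: str) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")


def parse_profile(obj: Any, where: str = "profile") -> BehaviourProfile:
    obj = _require_mapping(obj, where)
    _reject_unknown(obj, PROFILE_KEYS, where)
    try:
        return BehaviourProfile(**obj)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def parse_intervention(obj: Any, where: str) -> Intervention:
    obj = _require_mapping(obj, where)
    _reject_unknown(obj, INTERVENTION_KEYS, where)
    if "kind" not in obj:
        raise ConfigError(f"{where}: missing required key 'kind'")
    if "coverage" not in obj:
        raise ConfigError(f"{where}: missing required key 'coverage'")
    kwargs = dict(obj)
    if "targets" in kwargs:
        kwargs["targets"] = frozenset(kwargs["targets"])
    try:
        return Intervention(**kwargs)
    except (TypeError, ValueError, KeyError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def parse_scenario(obj: Any) -> tuple[BehaviourProfile, list[Intervention]]:
    """Parse a scenario document: a profile plus an ordered stack."""
    obj = _require_mapping(obj, "scenario")
    _reject_unknown(obj, SCENARIO_KEYS, "scenario")
    if "profile" not in obj:
        raise ConfigError("scenario: missing required key 'profile'")
    profile = parse_profile(obj["profile"])
    raw = obj.get("interventions", []) or []
    if not isinstance(raw, list):
        raise ConfigError("scenario.interventions: expected a list")
    stack = [
        parse_intervention(item, f"scenario.interventions[{i}]")
        for i, item in enumerate(raw)
    ]
    return profile, stack


def load_scenario(path: str | Path) -> tuple[BehaviourProfile, list[Intervention]]:
    return parse_scenario(load_document(path))


def parse_synth_config(obj: Any, seed: int | None = None) -> SynthConfig:
    obj = _require_mapping(obj, "synth")
    _reject_unknown(obj, SYNTH_KEYS, "synth")
    kwargs = dict(obj)
    if "peak_weights" in kwargs:
        kwargs["peak_weights"] = tuple(kwargs["peak_weights"])
    if seed is not None:
        kwargs["seed"] = int(seed)
    try:
        return SynthConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"synth: {exc}") from exc


def load_synth_config(path: str | Path, seed: int | None = None) -> SynthConfig:
    return parse_synth_config(load_document(path), seed=seed)
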