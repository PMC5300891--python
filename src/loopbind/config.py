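"""Scenario configuration: YAML/JSON loading with unit-tagged overrides.

A config file is a mapping with any of the keys ``scenario``,
``parameters``, ``conditions``, ``integrator``, ``seed`` and ``out_dir``.
Numeric overrides inside ``parameters`` and ``conditions`` are unit-tagged
(``{value: 3.0e4, unit: "1/(M*s)"}``) or bare SI numbers.  Anything not
overridden falls back to the reference Zipcode parameter set and base
concentrations; unknown keys are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .model import (
    KineticParameters,
    MixtureConditions,
    ZIPCODE_CONDITIONS,
    ZIPCODE_KH34_PARAMETERS,
)
from .simulate import IntegratorSettings

__all__ = ["ScenarioConfig", "load_config", "DEFAULT_SCENARIO"]

DEFAULT_SCENARIO = "base_timecourse"

_TOP_LEVEL_KEYS = {"scenario", "parameters", "conditions", "integrator",
                   "seed", "out_dir"}
_INTEGRATOR_KEYS = {"dt", "t_end", "equilibrium_tol", "store_every"}


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully resolved scenario: name, parameters, conditions, settings."""

    scenario: str = DEFAULT_SCENARIO
    params: KineticParameters = field(default=ZIPCODE_KH34_PARAMETERS)
    conditions: MixtureConditions = field(default=ZIPCODE_CONDITIONS)
    settings: IntegratorSettings = field(
        default_factory=lambda: IntegratorSettings(t_end=2000.0))
    out_dir: str = "."
    seed: int | None = None

    def resolved_dict(self) -> dict:
        """Complete parameter log for reproducibility."""
        return {
            "scenario": self.scenario,
            "parameters": self.params.to_dict(),
            "conditions": self.conditions.to_dict(),
            "integrator": {
                "dt": self.settings.dt,
                "t_end": self.settings.t_end,
                "equilibrium_tol": self.settings.equilibrium_tol,
                "store_every": self.settings.store_every,
            },
            "out_dir": self.out_dir,
            "seed": self.seed,
        }


def _merge_params(overrides: dict) -> KineticParameters:
    base = ZIPCODE_KH34_PARAMETERS.to_dict()
    base.update(overrides)
    return KineticParameters.from_dict(base)


def _merge_conditions(overrides: dict) -> MixtureConditions:
    base = ZIPCODE_CONDITIONS.to_dict()
    base.update(overrides)
    return MixtureConditions.from_dict(base)


def _merge_integrator(overrides: dict) -> IntegratorSettings:
    unknown = set(overrides) - _INTEGRATOR_KEYS
    if unknown:
        raise ConfigError(f"unknown integrator key(s): {sorted(unknown)}")
    merged = {"t_end": 2000.0}  # generous default horizon for equilibration
    merged.update(overrides)
    return IntegratorSettings(**merged)


def parse_config(raw: dict | None, **cli_overrides) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from parsed mapping + CLI overrides."""
    raw = dict(raw or {})
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    merged = {**raw, **{k: v for k, v in cli_overrides.items()
                        if v is not None}}
    try:
        return ScenarioConfig(
            scenario=merged.get("scenario", DEFAULT_SCENARIO),
            params=_merge_params(merged.get("parameters", {}) or {}),
            conditions=_merge_conditions(merged.get("conditions", {}) or {}),
            settings=_merge_integrator(merged.get("integrator", {}) or {}),
            out_dir=str(merged.get("out_dir", ".")),
            seed=merged.get("seed"),
        )
    except ConfigError:
        raise
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path, **cli_overrides) -> ScenarioConfig:
    """Load a YAML or JSON config file and fill defaults.

    An empty file yields the full reference scenario.  Malformed units or
    out-of-domain values raise :class:`ConfigError` naming the field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return parse_config(raw, **cli_overrides)
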