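"""Run configuration: YAML loading, validation, and study defaults.

An empty config reproduces the study defaults: all six renal stages, doses
{2,4,6,8,10} mg/kg as 5-min infusions q24h for three days, the MIC panel
{0.25,...,8} ug/mL, PTA >= 90% / risk <= 10% decision thresholds, and a
desk-scale population of n=2,000 per stage (set ``population.n: 10000`` for
the full-scale grid).  Unknown keys are rejected by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigurationError
from .pbpk import DrugParameters
from .physiology import HEALTHY_GFR_ML_MIN_KG, RENAL_STAGES, STAGE_ORDER
from .pkpd import MIC_GRID

__all__ = ["RunConfig", "PopulationConfig", "RegimenConfig", "TargetConfig", "load_config", "config_to_dict"]


@dataclass(frozen=True)
class PopulationConfig:
    n: int = 2000
    weight_range: tuple[float, float] = (8.0, 12.0)
    stages: tuple[str, ...] = STAGE_ORDER
    cv_gfr: float = 0.15
    seed: int = 0
    gfr_healthy: float = HEALTHY_GFR_ML_MIN_KG

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("population.n must be >= 1")
        lo, hi = self.weight_range
        if not 0 < lo <= hi:
            raise ConfigurationError("population.weight_range must satisfy 0 < lo <= hi")
        for s in self.stages:
            if s not in RENAL_STAGES:
                raise ConfigurationError(f"unknown stage {s!r} in population.stages")
        if self.cv_gfr < 0:
            raise ConfigurationError("population.cv_gfr must be >= 0")


@dataclass(frozen=True)
class RegimenConfig:
    doses: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0)
    intervals: tuple[float, ...] = (24.0,)
    n_doses: int = 3
    infusion_h: float = 5.0 / 60.0

    def __post_init__(self) -> None:
        if not self.doses or any(d < 0 for d in self.doses):
            raise ConfigurationError("regimen.doses must be non-empty and >= 0")
        if not self.intervals or any(i <= 0 for i in self.intervals):
            raise ConfigurationError("regimen.intervals must be non-empty and > 0")
        if self.n_doses < 1:
            raise ConfigurationError("regimen.n_doses must be >= 1")
        if self.infusion_h < 0:
            raise ConfigurationError("regimen.infusion_h must be >= 0")


@dataclass(frozen=True)
class TargetConfig:
    mic_grid: tuple[float, ...] = MIC_GRID
    cmax_threshold: float = 10.0
    auc_thresholds: tuple[float, ...] = (50.0, 110.0)
    pta_threshold: float = 90.0
    risk_threshold: float = 10.0

    def __post_init__(self) -> None:
        if not self.mic_grid or any(m <= 0 for m in self.mic_grid):
            raise ConfigurationError("targets.mic_grid must be positive")
        if not 0 < self.pta_threshold <= 100:
            raise ConfigurationError("targets.pta_threshold must be in (0, 100]")
        if not 0 <= self.risk_threshold <= 100:
            raise ConfigurationError("targets.risk_threshold must be in [0, 100]")


@dataclass(frozen=True)
class RunConfig:
    drug: DrugParameters = DrugParameters()
    population: PopulationConfig = PopulationConfig()
    regimen: RegimenConfig = RegimenConfig()
    targets: TargetConfig = TargetConfig()
    output_dir: str = "results/pipeline"


_SECTIONS = {
    "drug": DrugParameters,
    "population": PopulationConfig,
    "regimen": RegimenConfig,
    "targets": TargetConfig,
}
_LIST_FIELDS = {
    "weight_range",
    "stages",
    "doses",
    "intervals",
    "mic_grid",
    "auc_thresholds",
}


def _build_section(name: str, cls, payload: Mapping) -> object:
    if not isinstance(payload, Mapping):
        raise ConfigurationError(f"section {name!r} must be a mapping")
    valid = set(cls.__dataclass_fields__)
    unknown = set(payload) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in section {name!r}"
        )
    kwargs = {}
    for key, value in payload.items():
        if key in _LIST_FIELDS and isinstance(value, Sequence) and not isinstance(value, str):
            value = tuple(value)
        if key == "kp_overrides" and value is not None:
            value = dict(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid section {name!r}: {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``None`` or an empty file yields the study defaults.  Unknown sections
    or keys raise :class:`ConfigurationError` naming the offender.
    """
    payload: Mapping = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigurationError("top-level config must be a mapping")
        payload = loaded
    known = set(_SECTIONS) | {"output_dir"}
    unknown = set(payload) - known
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s) {sorted(unknown)}")
    sections = {
        name: _build_section(name, cls, payload.get(name, {}))
        for name, cls in _SECTIONS.items()
    }
    output_dir = payload.get("output_dir", RunConfig.output_dir)
    if not isinstance(output_dir, str):
        raise ConfigurationError("output_dir must be a string")
    return RunConfig(output_dir=output_dir, **sections)


def config_to_dict(config: RunConfig) -> dict:
    """Effective configuration as a plain dict (for the run echo)."""
    out = asdict(config)
    out["drug"]["kp_overrides"] = dict(config.drug.kp_overrides)
    return out
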