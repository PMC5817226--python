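"""Design-configuration schema, loading and hashing.

A study is configured once, from a YAML (or JSON) file: factors with their
physical ranges and gene lengths, objectives with direction and weight, and
the GA parameters.  The configuration is schema-validated at load time and
immutable afterwards — the session refuses to run against a state file whose
configuration hash has changed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .design_space import DesignSpace, FactorSpec, ObjectiveSpec, population_size_rule
from .errors import ConfigError
from .ga import GAParams

__all__ = ["StudyConfig", "load_config", "build_spaces", "config_hash"]


class FactorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    min: float
    max: float
    bits: int = 5
    units: str = ""


class ObjectiveConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    direction: str = "maximize"
    weight: float = 1.0


class GAConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    population_size: Optional[int] = None  # default: 2n - 2
    selection_fraction: float = 0.5
    crossover_rate: float = 0.9
    mutation_rate: float = 0.01
    elitism: int = 0
    gray_code: bool = False


class StudyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    factors: list[FactorConfig] = Field(min_length=1)
    objectives: list[ObjectiveConfig] = Field(min_length=1)
    ga: GAConfig = GAConfig()
    seed: int = 0


def load_config(source: Union[str, Path, dict]) -> StudyConfig:
    """Parse and validate a study configuration (YAML/JSON file or dict)."""
    if isinstance(source, (str, Path)):
        try:
            raw = yaml.safe_load(Path(source).read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse configuration file: {e}") from e
    else:
        raw = source
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    try:
        return StudyConfig.model_validate(raw)
    except ValidationError as e:
        items = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in e.errors()
        )
        raise ConfigError(f"invalid configuration: {items}") from e


def build_spaces(cfg: StudyConfig) -> tuple[DesignSpace, GAParams]:
    """Materialise the validated configuration into domain objects."""
    try:
        space = DesignSpace(
            factors=[
                FactorSpec(f.name, f.min, f.max, f.bits, f.units)
                for f in cfg.factors
            ],
            objectives=[
                ObjectiveSpec(o.name, o.direction, o.weight) for o in cfg.objectives
            ],
            gray_code=cfg.ga.gray_code,
        )
        pop = cfg.ga.population_size
        if pop is None:
            pop = population_size_rule(len(cfg.factors))
        params = GAParams(
            population_size=pop,
            selection_fraction=cfg.ga.selection_fraction,
            crossover_rate=cfg.ga.crossover_rate,
            mutation_rate=cfg.ga.mutation_rate,
            elitism=cfg.ga.elitism,
            seed=cfg.seed,
        )
    except ValueError as e:
        raise ConfigError(str(e)) from e
    return space, params


def config_hash(cfg: StudyConfig) -> str:
    """Stable digest of the canonicalised configuration."""
    canonical = json.dumps(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
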