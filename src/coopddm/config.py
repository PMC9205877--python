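"""Study configuration: a versioned, fully validated schema for every stage.

The configuration is plain YAML with four sections (task, cohort, fit,
stats) plus a root seed.  Unknown keys are rejected and every numeric field
is range-checked before any stage runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cohort import EffectConfig, TraitConfig
from .task import PayoffMatrix

__all__ = ["StudyConfig", "ConfigurationError", "validate_and_load", "default_config"]

SCHEMA_VERSION = 1


class ConfigurationError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PayoffSection(_Strict):
    cc: int = 20
    cd: int = 0
    dc: int = 30
    dd: int = 5

    def to_matrix(self) -> PayoffMatrix:
        return PayoffMatrix(cc=self.cc, cd=self.cd, dc=self.dc, dd=self.dd)


class TaskSection(_Strict):
    payoff: PayoffSection = PayoffSection()
    #: enforce the design constraint that deception strictly dominates
    enforce_deception_dominance: bool = True
    p_cooperative: float = Field(0.7, ge=0.0, le=1.0)
    p_deceitful: float = Field(0.3, ge=0.0, le=1.0)
    p_random: float = Field(0.5, ge=0.0, le=1.0)
    tft_first_move: str = Field("mirror", pattern="^(mirror|cooperate|deceive)$")
    time_limit_s: float = Field(10.0, gt=0.0)
    opponent_rt_min_s: float = Field(1.0, gt=0.0)
    opponent_rt_max_s: float = Field(3.0, gt=0.0)

    @model_validator(mode="after")
    def _check(self):
        if self.opponent_rt_max_s <= self.opponent_rt_min_s:
            raise ValueError("opponent_rt_max_s must exceed opponent_rt_min_s")
        if self.enforce_deception_dominance:
            self.payoff.to_matrix().check_deception_dominant()
        return self


class EffectSection(_Strict):
    boundary: float = Field(1.6, gt=0.0)
    nondecision: float = Field(0.35, ge=0.0)
    drift_sham: float = -0.3463
    bias_shift_tvns: float = 0.075
    drift_shift_tvns: float = 0.011
    neuroticism_modulation: float = -0.9
    extraversion_modulation: float = 0.2
    subject_drift_sd: float = Field(0.32, ge=0.0)
    invalid_rate: float = Field(0.0035, ge=0.0, lt=1.0)
    reciprocity: float = 0.0
    dt: float = Field(1e-3, gt=0.0)
    bridge: bool = False
    likability_human_mean: float = Field(6.2, ge=1.0, le=9.0)
    likability_computer_mean: float = Field(4.2, ge=1.0, le=9.0)
    likability_sd: float = Field(1.3, gt=0.0)

    def to_effect(self) -> EffectConfig:
        return EffectConfig(**self.model_dump())


class TraitSection(_Strict):
    age_mean: float = Field(45.0, gt=0.0)
    age_sd: float = Field(12.0, gt=0.0)
    p_female: float = Field(13 / 19, ge=0.0, le=1.0)
    neo_mean: float = 50.0
    neo_sd: float = Field(10.0, gt=0.0)
    p_believed_live: float = Field(12 / 19, ge=0.0, le=1.0)

    def to_traits(self) -> TraitConfig:
        return TraitConfig(**self.model_dump())


class CohortSection(_Strict):
    n_subjects: int = Field(19, ge=2)
    traits: TraitSection = TraitSection()
    effect: EffectSection = EffectSection()


class FitSection(_Strict):
    objective: str = Field("ml", pattern="^(ml|qmle)$")
    restarts: int = Field(3, ge=1)
    rt_floor: float = Field(0.2, ge=0.0)
    min_trials: int = Field(10, ge=1)
    grouping: str = "stim_condition"
    free_params: tuple[str, ...] = ("a", "t0", "eta", "b", "sz", "st", "v")


class StatsSection(_Strict):
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    r2_threshold: float = Field(0.7, gt=0.0, le=1.0)
    bonferroni_m: Optional[int] = Field(None, ge=1)
    power_target: float = Field(0.95, gt=0.0, lt=1.0)
    agq: int = Field(7, ge=1)


class StudyConfig(_Strict):
    schema_version: int = SCHEMA_VERSION
    seed: int = Field(0, ge=0)
    task: TaskSection = TaskSection()
    cohort: CohortSection = CohortSection()
    fit: FitSection = FitSection()
    stats: StatsSection = StatsSection()

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)


def default_config() -> StudyConfig:
    return StudyConfig()


def validate_and_load(path) -> StudyConfig:
    """Load and validate a YAML study configuration, filling defaults.

    Raises ConfigurationError naming the offending key and constraint.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    except yaml.YAMLError as e:
        raise ConfigurationError(f"config is not valid YAML: {e}") from e
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    try:
        return StudyConfig(**data)
    except ValidationError as e:
        msgs = []
        for err in e.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            msgs.append(f"{loc}: {err['msg']}")
        raise ConfigurationError("invalid configuration: " + "; ".join(msgs)) from e
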