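"""Experiment configuration: schema-validated, defaults = the platform's printed values."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .calibration import GREY_MIN_USABLE, LOG_LUM_MAX, LOG_LUM_MIN
from .lens import FAST_RATE, SENSOR_DELAY, SENSOR_THRESHOLD, SLOW_RATE, LensSpec, SwitchingProfile
from .observer import ObserverParams

__all__ = ["ExperimentConfig", "LensConfig", "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CalibrationConfig(_Strict):
    source: str = "preset"  # "preset" or a path to a sweep CSV
    grey_min: int = Field(GREY_MIN_USABLE, ge=0, lt=255)
    log_lum_min: float = LOG_LUM_MIN
    log_lum_max: float = LOG_LUM_MAX

    @model_validator(mode="after")
    def _range_ok(self):
        if self.log_lum_min >= self.log_lum_max:
            raise ValueError("log_lum_min must be below log_lum_max")
        return self


class LensConfig(_Strict):
    label: str
    mode: Literal["static", "self_tinting"]
    static_transmission: Optional[float] = Field(None, gt=0, le=1)
    shape: Literal["exponential", "linear"] = "exponential"
    t_max: float = Field(0.9, gt=0, le=1)
    t_min: float = Field(0.1, gt=0, lt=1)
    rate: float = Field(FAST_RATE, gt=0)
    delay: float = Field(SENSOR_DELAY, ge=0)
    sensor_threshold: float = Field(SENSOR_THRESHOLD, gt=0)

    def to_spec(self) -> LensSpec:
        if self.mode == "static":
            return LensSpec(
                mode="static",
                static_transmission=self.static_transmission,
                sensor_threshold=self.sensor_threshold,
                label=self.label,
            )
        profile = SwitchingProfile(
            shape=self.shape, t_max=self.t_max, t_min=self.t_min, rate=self.rate, delay=self.delay
        )
        return LensSpec(
            mode="self_tinting",
            profile=profile,
            sensor_threshold=self.sensor_threshold,
            label=self.label,
        )


def _default_lenses() -> List[LensConfig]:
    return [
        LensConfig(label="self_tint_fast", mode="self_tinting", rate=FAST_RATE),
        LensConfig(label="self_tint_slow", mode="self_tinting", rate=SLOW_RATE),
        LensConfig(label="normal", mode="static", static_transmission=0.95),
        LensConfig(label="sunglasses", mode="static", static_transmission=0.20),
    ]


class SessionConfig(_Strict):
    trials_per_direction: int = Field(20, ge=1)
    ramp_rates: List[float] = Field(default_factory=lambda: [3.0, 1.0])
    isi: float = Field(4.0, ge=0)
    frame_rate: float = Field(90.0, gt=0)
    n_participants: int = Field(1, ge=1)

    @model_validator(mode="after")
    def _rates_ok(self):
        if any(r <= 0 for r in self.ramp_rates):
            raise ValueError("ramp rates must be positive")
        return self


class ObserverConfig(_Strict):
    contrast_threshold: float = Field(ObserverParams.contrast_threshold, gt=0)
    motor_latency: float = Field(ObserverParams.motor_latency, gt=0)
    latency_sd: float = Field(ObserverParams.latency_sd, ge=0)
    adaptation_tau_dark: float = Field(ObserverParams.adaptation_tau_dark, gt=0)
    adaptation_tau_light: float = Field(ObserverParams.adaptation_tau_light, gt=0)
    penalty_gain: float = Field(ObserverParams.penalty_gain, ge=0)
    penalty_exponent: float = Field(ObserverParams.penalty_exponent, gt=0)
    lum_half: float = Field(ObserverParams.lum_half, gt=0)
    lum_scotopic: float = Field(ObserverParams.lum_scotopic, gt=0)
    scotopic_slowdown: float = Field(ObserverParams.scotopic_slowdown, ge=0)

    def to_params(self, seed: int = 0) -> ObserverParams:
        return ObserverParams(seed=seed, **self.model_dump())


class ExperimentConfig(_Strict):
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    lenses: List[LensConfig] = Field(default_factory=_default_lenses)
    session: SessionConfig = Field(default_factory=SessionConfig)
    observer: ObserverConfig = Field(default_factory=ObserverConfig)
    seed: int = 0
    output_dir: str = "results"

    def conditions(self):
        return [(lens.to_spec(), rate) for lens in self.lenses for rate in self.session.ramp_rates]


def load_config(path: Optional[Path | str]) -> ExperimentConfig:
    """Load a YAML or JSON config; None or an empty file yields full defaults.

    Unknown keys are rejected with the offending key named.
    """
    if path is None:
        return ExperimentConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if data is None:
        data = {}
    try:
        return ExperimentConfig.model_validate(data)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(config: ExperimentConfig, path: Optional[Path | str] = None) -> str:
    text = yaml.safe_dump(config.model_dump(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
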