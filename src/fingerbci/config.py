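"""Session configuration: a validated, round-trippable YAML surface.

Every stochastic component of a session derives its seed from the single
global seed here, so a session is fully reproducible from its config file.
Unknown keys are rejected; validation errors name the offending field.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "ConfigError",
    "PopulationSettings",
    "DecoderSettings",
    "TaskSettings",
    "ScheduleSettings",
    "QuadSettings",
    "SessionConfig",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=False)


class PopulationSettings(_Strict):
    n_channels: int = Field(192, gt=0)
    dof: Literal[1, 2, 3, 4] = 4
    tuning_sd: float = Field(1.0, ge=0)
    noise_sd: float = Field(2.0, ge=0)
    interaction_scale: float = Field(0.0, ge=0)
    baseline: float = 1.0


class DecoderSettings(_Strict):
    n_time_features: int = Field(16, gt=0)
    hidden_widths: tuple[int, int, int] = (256, 256, 256)
    dropout_rate: float = Field(0.5, ge=0, lt=1)
    speed_scale: float = Field(1.0, gt=0)
    learning_rate: float = Field(1e-3, gt=0)
    epochs: int = Field(200, gt=0)
    batch_size: int = Field(64, ge=2)
    refit_learning_rate: float = Field(1e-4, gt=0)
    refit_weight_decay: float = Field(1e-2, ge=0)
    refit_iterations: int = Field(500, gt=0)


class TaskSettings(_Strict):
    kind: Literal["cl2d", "cl4d_two_new", "cl4d_one_new", "cl4d_random", "t_train"] = "cl2d"
    width: float = Field(0.20, gt=0, lt=1)
    hold_s: Optional[float] = None
    timeout_s: Optional[float] = None
    user_speed: float = Field(1.0, gt=0)
    motor_noise_sd: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _hold_within_timeout(self):
        if self.hold_s is not None and self.timeout_s is not None:
            if self.hold_s > self.timeout_s:
                raise ValueError(
                    f"hold_s ({self.hold_s}) must not exceed timeout_s ({self.timeout_s})"
                )
        return self


class ScheduleSettings(_Strict):
    open_loop_trials: int = Field(40, gt=0)
    rest_trials: int = Field(8, ge=0)
    closed_loop_trials: int = Field(50, gt=0)
    refit_rounds: int = Field(2, ge=0)
    t_train_gate: float = Field(0.8, ge=0, le=1)  # success rate to advance to 4T
    max_t_train_rounds: int = Field(3, ge=0)


class QuadSettings(_Strict):
    gains: tuple[float, float, float, float] = (0.6, 0.8, 0.4, 0.6)
    max_linear_speed: float = Field(10.0, gt=0)
    max_yaw_rate: float = Field(90.0, gt=0)
    neutral_zone: float = Field(0.10, gt=0, lt=0.5)
    gravity_amplitude: float = Field(0.05, ge=0)


class SessionConfig(_Strict):
    task: TaskSettings = TaskSettings()
    population: PopulationSettings = PopulationSettings()
    decoder: DecoderSettings = DecoderSettings()
    schedule: ScheduleSettings = ScheduleSettings()
    quad: QuadSettings = QuadSettings()
    seed: int = 0

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> SessionConfig:
    """Parse and validate a YAML session config; defaults fill missing keys."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse error: {exc}") from exc
    if data is None:
        data = {}
    try:
        return SessionConfig(**data)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: invalid config ({locs})") from exc


def save_config(config: SessionConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )
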