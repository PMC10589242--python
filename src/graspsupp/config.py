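"""Run configuration: every fixed constant of the analysis lives here exactly once."""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, Field

from .kinematics import FilterSpec
from .synthdata import GraspPolicy, ObjectModel, ObserverModel

__all__ = ["RunConfig", "FilterSettings", "PsychometricSettings", "PolicySettings", "ObserverSettings", "ObjectSettings"]


class FilterSettings(BaseModel):
    order: int = 2
    cutoff: float = 0.3
    mode: Literal["fraction_nyquist", "hz"] = "fraction_nyquist"

    def to_spec(self) -> FilterSpec:
        return FilterSpec(order=self.order, cutoff=self.cutoff, mode=self.mode)


class PsychometricSettings(BaseModel):
    gamma_max: float = 0.30
    lapse_max: float = 0.05
    threshold_criterion: Literal["midpoint", "absolute"] = "midpoint"


class PolicySettings(BaseModel):
    separation_amplitude: float = 0.8
    rule: Literal["predictive", "anti_predictive", "random"] = "predictive"
    kinematic_noise_sd: float = 0.08
    loading_time_ms: dict[str, float] = Field(
        default_factory=lambda: {"MD_same": 300.0, "MD_different": 250.0}
    )
    loading_jitter_sd_ms: float = 40.0

    def to_policy(self) -> GraspPolicy:
        return GraspPolicy(
            separation_amplitude=self.separation_amplitude,
            rule=self.rule,
            kinematic_noise_sd=self.kinematic_noise_sd,
            loading_time_ms=dict(self.loading_time_ms),
            loading_jitter_sd_ms=self.loading_jitter_sd_ms,
        )


class ObjectSettings(BaseModel):
    roll_gain: float = 1.0
    roll_rise_ms: float = 200.0
    roll_noise_sd_deg: float = 0.8

    def to_object(self) -> ObjectModel:
        return ObjectModel(
            roll_gain=self.roll_gain,
            roll_rise_ms=self.roll_rise_ms,
            roll_noise_sd_deg=self.roll_noise_sd_deg,
        )


class ObserverSettings(BaseModel):
    guess_rate: float = 0.10
    lapse_rate: float = 0.02
    baseline_threshold_um: float = 18.0
    width_um: float = 20.0
    threshold_shift_um: dict[str, float] = Field(
        default_factory=lambda: {
            "baseline": 0.0,
            "MD_same": 10.0,
            "MD_different": 10.0,
            "constant": 10.0,
            "mixed": 10.0,
            "practice": 10.0,
        }
    )

    def to_observer(self) -> ObserverModel:
        return ObserverModel(
            guess_rate=self.guess_rate,
            lapse_rate=self.lapse_rate,
            baseline_threshold_um=self.baseline_threshold_um,
            width_um=self.width_um,
            threshold_shift_um=dict(self.threshold_shift_um),
        )


class RunConfig(BaseModel):
    """Everything a deterministic end-to-end run needs."""

    experiment: Literal["exp1", "exp2"] = "exp1"
    n_participants: int = 24
    seed: int = 0
    filter: FilterSettings = Field(default_factory=FilterSettings)
    speed_threshold_cm_s: float = 10.0
    separation_window_ms: float = 100.0
    roll_window_ms: float = 250.0
    false_alarm_cutoff: float = 0.30
    psychometric: PsychometricSettings = Field(default_factory=PsychometricSettings)
    policy: PolicySettings = Field(default_factory=PolicySettings)
    observer: ObserverSettings = Field(default_factory=ObserverSettings)
    object: ObjectSettings = Field(default_factory=ObjectSettings)
    out_dir: str | None = None

    def to_object_model(self) -> ObjectModel:
        return self.object.to_object()
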