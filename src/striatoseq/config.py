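"""Structured experiment configuration (YAML) with validated defaults.

A minimal config needs only the task id; every other field defaults to
the simulation constants used throughout the package (dt = 0.1 ms,
ε = 0.02, τ_s = 20 ms, A_reward = 0.9, t_duration = 50 ms, …). Unknown
fields are rejected with the offending field path, and a loaded config
re-serializes to itself.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .neurons import M1Params, M2Params, SynapseKernel
from .patterns import TaskConfig
from .plasticity import RewardRule, STDPRule, STDP_PRESETS
from .protocol import NetworkConfig, TrainConfig

__all__ = ["ExperimentConfig", "load_config", "dump_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TaskSection(_Strict):
    id: Literal[1, 2, 3, 4] = 1
    P: int = 10
    N_p: int = 5
    N_stim: int = 3
    t_delay: Optional[float] = None  # 1 ms (Task 1/3), 0.5 ms (Task 2)
    tau_pattern: float = 0.0
    lambda_poisson: float = 1.0
    t_poisson: float = 2.0
    lambda_stim: float = 0.0
    lambda_ext: float = 0.0
    t_offset: float = 10.0
    t_duration: float = 50.0
    reward_prob: float = 0.5

    def to_runtime(self) -> TaskConfig:
        t_delay = self.t_delay if self.t_delay is not None else (0.5 if self.id == 2 else 1.0)
        return TaskConfig(
            P=self.P,
            N_p=self.N_p,
            N_stim=self.N_stim,
            t_delay=t_delay,
            tau_pattern=self.tau_pattern,
            lambda_poisson=self.lambda_poisson,
            t_poisson=self.t_poisson,
            lambda_stim=self.lambda_stim,
            lambda_ext=self.lambda_ext,
            t_offset=self.t_offset,
            t_duration=self.t_duration,
            reward_prob=self.reward_prob,
        )


class KernelSection(_Strict):
    kind: Literal["dirac", "exponential", "alpha"] = "dirac"
    T_s: float = 10.0

    def to_runtime(self) -> SynapseKernel:
        return SynapseKernel(self.kind, self.T_s)


class NetworkSection(_Strict):
    model: Literal["m1", "m2"] = "m1"
    kernel: KernelSection = Field(default_factory=KernelSection)
    n_msn: Literal[1, 2] = 1
    J: float = -0.5
    reward_scheme: Literal["differential", "same"] = "differential"
    w_init: tuple[float, float] = (0.0, 0.05)
    w_min: float = 0.0
    w_max: float = 2.0
    v_noise: bool = True

    def to_runtime(self) -> NetworkConfig:
        return NetworkConfig(
            model=M1Params() if self.model == "m1" else M2Params(),
            kernel=self.kernel.to_runtime(),
            n_msn=self.n_msn,
            J=self.J,
            reward_scheme=self.reward_scheme,
            w_init=self.w_init,
            w_min=self.w_min,
            w_max=self.w_max,
            v_noise=self.v_noise,
        )


class PlasticitySection(_Strict):
    rule: Literal["symmetric-ltd", "hebbian", "anti-hebbian", "symmetric-ltp"] = (
        "anti-hebbian"
    )
    tau_stdp: float = 20.0
    epsilon: float = 0.02
    A_reward: float = 0.9

    def to_runtime(self) -> tuple[STDPRule, RewardRule]:
        preset = STDP_PRESETS[self.rule]
        stdp = STDPRule(
            preset.A_post_pre, preset.A_pre_post, self.tau_stdp, self.epsilon
        )
        return stdp, RewardRule(self.A_reward)


class TrainingSection(_Strict):
    n_iterations: int = 500
    test_every: Optional[int] = None
    T_1: int = 10
    n_repetitions: int = 250
    dt: float = 0.1

    def to_runtime(self) -> TrainConfig:
        return TrainConfig(
            n_iterations=self.n_iterations,
            test_every=self.test_every,
            T_1=self.T_1,
            n_repetitions=self.n_repetitions,
            dt=self.dt,
        )


class SweepAxis(_Strict):
    path: str  # dotted config path, e.g. "plasticity.rule"
    values: list

    @field_validator("values")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("sweep axis needs at least one value")
        return v


class ExperimentConfig(_Strict):
    """Full nested experiment description; YAML round-trip safe."""

    task: TaskSection = Field(default_factory=TaskSection)
    network: NetworkSection = Field(default_factory=NetworkSection)
    plasticity: PlasticitySection = Field(default_factory=PlasticitySection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    sweep: list[SweepAxis] = Field(default_factory=list)
    seed: int = 0
    out_dir: str = "results"

    def with_override(self, path: str, value) -> "ExperimentConfig":
        data = self.model_dump()
        node = data
        *parents, leaf = path.split(".")
        for key in parents:
            node = node[key]
        if leaf not in node:
            raise KeyError(f"unknown config field {path!r}")
        node[leaf] = value
        return ExperimentConfig.model_validate(data)


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ExperimentConfig.model_validate(data)


def dump_config(cfg: ExperimentConfig) -> str:
    """Canonical YAML serialization (stable key order)."""
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)


def config_hash(cfg: ExperimentConfig) -> str:
    """Short digest embedded in every output artifact for replay."""
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:12]
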