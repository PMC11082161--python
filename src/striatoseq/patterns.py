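"""Cortical spike-pattern generators: the four task families and noise.

A *pattern* is a fixed spatio-temporal template of cortical spikes
presented within a trial of ``t_duration`` ms (default 50), with the
correlated activity starting at ``t_offset``. Each pattern carries a
reward flag; during training, rewarded patterns engage reward-LTP.

Task families:

* **Task 1** — sequences with a fixed inter-spike delay (1 ms): the
  number of spikes is uniform in {1..N_stim}, channels drawn without
  replacement in random order.
* **Task 2** — the full nested family (1), (1,2), …, (1,…,P) with a
  0.5 ms delay, evaluated over all 2^P reward assignments.
* **Task 3** — Task-1 templates whose spike times are jittered at every
  presentation by a uniform shift of standard deviation ``tau_pattern``.
* **Task 4** — Poisson bursts at ``lambda_poisson`` (kHz) over
  ``t_poisson`` ms, conditioned on at least two spikes in total.

Background noise adds independent Poisson spikes on every cortical
channel (rate ``lambda_stim``) and on the external channel
(``lambda_ext``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from math import sqrt
from pathlib import Path
from typing import Sequence

import numpy as np

from .neurons import InputSpec

__all__ = [
    "Pattern",
    "TaskConfig",
    "gen_task1",
    "gen_task2_nested",
    "gen_task3_jitter",
    "jitter_pattern",
    "gen_task4_poisson",
    "subpatterns",
    "add_noise_spikes",
    "patterns_to_json",
    "patterns_from_json",
]


@dataclass(frozen=True)
class Pattern:
    """A deterministic spike template plus its reward flag.

    ``spikes`` is an ordered tuple of (channel, time_ms) with channels
    in 1..P; all times lie in [t_offset, t_duration].
    """

    spikes: tuple[tuple[int, float], ...]
    t_offset: float = 10.0
    t_duration: float = 50.0
    rewarded: bool = False

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(ch for ch, _ in self.spikes)

    @property
    def last_spike_time(self) -> float:
        if not self.spikes:
            return self.t_offset
        return max(t for _, t in self.spikes)

    def key(self) -> tuple:
        """Hashable identity of the template (channels and times)."""
        return self.spikes


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of a pattern-classification task.

    Rates: ``lambda_stim`` and ``lambda_ext`` in Hz, ``lambda_poisson``
    in kHz (so ``lambda_poisson * t_poisson`` is the expected burst spike
    count). ``reward_prob`` is the i.i.d. probability that a pattern is
    rewarded.
    """

    P: int = 10
    N_p: int = 5
    N_stim: int = 3
    t_delay: float = 1.0
    tau_pattern: float = 0.0
    lambda_poisson: float = 1.0
    t_poisson: float = 2.0
    lambda_stim: float = 0.0
    lambda_ext: float = 0.0
    t_offset: float = 10.0
    t_duration: float = 50.0
    reward_prob: float = 0.5

    def __post_init__(self) -> None:
        if not (1 <= self.N_stim <= self.P):
            raise ValueError("require 1 <= N_stim <= P")
        for name in ("lambda_poisson", "lambda_stim", "lambda_ext"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.reward_prob <= 1.0):
            raise ValueError("reward_prob must lie in [0, 1]")


def _draw_rewards(n: int, cfg: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.random(n) < cfg.reward_prob


def gen_task1(cfg: TaskConfig, rng: np.random.Generator) -> list[Pattern]:
    """Draw N_p distinct fixed-delay sequence patterns.

    Duplicate templates are rejected and re-drawn so that conflicting
    reward labels cannot make the task ill-posed.
    """
    patterns: list[Pattern] = []
    seen: set = set()
    rewards = _draw_rewards(cfg.N_p, cfg, rng)
    for k in range(cfg.N_p):
        for _ in range(10_000):
            n = int(rng.integers(1, cfg.N_stim + 1))
            chans = rng.choice(cfg.P, size=n, replace=False) + 1
            spikes = tuple(
                (int(ch), cfg.t_offset + j * cfg.t_delay) for j, ch in enumerate(chans)
            )
            if spikes not in seen:
                seen.add(spikes)
                break
        else:  # pragma: no cover - only reachable when N_p exhausts templates
            raise ValueError("could not draw N_p distinct patterns")
        patterns.append(
            Pattern(spikes, cfg.t_offset, cfg.t_duration, rewarded=bool(rewards[k]))
        )
    return patterns


def gen_task2_nested(
    P: int,
    t_delay: float = 0.5,
    t_offset: float = 10.0,
    t_duration: float = 50.0,
) -> tuple[list[Pattern], list[tuple[bool, ...]]]:
    """The nested family (1), (1,2), …, (1..P) and all 2^P reward maps.

    Pattern j contains channels 1..j spiking ``t_delay`` apart. The
    returned patterns carry ``rewarded=False``; apply an assignment with
    ``dataclasses.replace`` per experiment.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    patterns = []
    for j in range(1, P + 1):
        spikes = tuple((ch, t_offset + (ch - 1) * t_delay) for ch in range(1, j + 1))
        patterns.append(Pattern(spikes, t_offset, t_duration))
    assignments = [
        tuple(bool((mask >> j) & 1) for j in range(P)) for mask in range(2**P)
    ]
    return patterns, assignments


def jitter_pattern(p: Pattern, tau_pattern: float, rng: np.random.Generator) -> Pattern:
    """One jittered presentation of a template.

    Each spike time is shifted by an independent uniform draw on
    ``[-tau_pattern*sqrt(3), +tau_pattern*sqrt(3)]`` (standard deviation
    ``tau_pattern``), then clipped to [0, t_duration]. Spike order may
    change.
    """
    if tau_pattern == 0.0:
        return p
    half = tau_pattern * sqrt(3.0)
    shifted = []
    for ch, t in p.spikes:
        tt = float(np.clip(t + rng.uniform(-half, half), 0.0, p.t_duration))
        shifted.append((ch, tt))
    return replace(p, spikes=tuple(shifted))


def gen_task3_jitter(
    base: Sequence[Pattern], cfg: TaskConfig, rng: np.random.Generator
) -> list[Pattern]:
    """Jittered presentations of Task-1 templates (one per base pattern)."""
    return [jitter_pattern(p, cfg.tau_pattern, rng) for p in base]


def gen_task4_poisson(cfg: TaskConfig, rng: np.random.Generator) -> list[Pattern]:
    """Draw N_p Poisson-burst patterns with at least two spikes each.

    Spikes form a Poisson process of intensity ``lambda_poisson`` kHz on
    ``[t_offset, t_offset + t_poisson]``, each spike assigned a uniform
    channel; bursts with fewer than two spikes (summed over channels)
    are rejection-sampled.
    """
    patterns: list[Pattern] = []
    rewards = _draw_rewards(cfg.N_p, cfg, rng)
    mean_count = cfg.lambda_poisson * cfg.t_poisson
    for k in range(cfg.N_p):
        while True:
            n = int(rng.poisson(mean_count))
            if n >= 2:
                break
        times = np.sort(rng.uniform(0.0, cfg.t_poisson, size=n)) + cfg.t_offset
        chans = rng.integers(1, cfg.P + 1, size=n)
        spikes = tuple((int(c), float(t)) for c, t in zip(chans, times))
        patterns.append(
            Pattern(spikes, cfg.t_offset, cfg.t_duration, rewarded=bool(rewards[k]))
        )
    return patterns


def subpatterns(p: Pattern, rng: np.random.Generator) -> Pattern:
    """A random nonempty proper subpattern, spike times preserved."""
    n = len(p.spikes)
    if n < 2:
        raise ValueError("a single-spike pattern has no proper subpattern")
    keep = int(rng.integers(1, n))  # 1 .. n-1 spikes retained
    idx = np.sort(rng.choice(n, size=keep, replace=False))
    return replace(p, spikes=tuple(p.spikes[i] for i in idx))


def add_noise_spikes(
    p: Pattern, cfg: TaskConfig, rng: np.random.Generator, v_noise: bool = False
) -> InputSpec:
    """Merge a pattern with its trial's Poisson background.

    Homogeneous background at ``lambda_stim`` Hz on each of the P
    cortical channels and ``lambda_ext`` Hz on the external channel,
    over the whole trial [0, t_duration].
    """
    events = list(p.spikes)
    if cfg.lambda_stim > 0:
        n_bg = rng.poisson(cfg.lambda_stim / 1000.0 * cfg.t_duration * cfg.P)
        for _ in range(int(n_bg)):
            events.append(
                (int(rng.integers(1, cfg.P + 1)), float(rng.uniform(0, cfg.t_duration)))
            )
    external: list[float] = []
    if cfg.lambda_ext > 0:
        n_ext = rng.poisson(cfg.lambda_ext / 1000.0 * cfg.t_duration)
        external = sorted(float(rng.uniform(0, cfg.t_duration)) for _ in range(int(n_ext)))
    events.sort(key=lambda e: e[1])
    return InputSpec(cortical=tuple(events), external=tuple(external), v_noise=v_noise)


def patterns_to_json(patterns: Sequence[Pattern], cfg: TaskConfig | None = None) -> str:
    """Serialize a pattern set (and optionally its config) to JSON."""
    payload = {
        "patterns": [
            {
                "spikes": [[ch, t] for ch, t in p.spikes],
                "t_offset": p.t_offset,
                "t_duration": p.t_duration,
                "rewarded": p.rewarded,
            }
            for p in patterns
        ],
    }
    if cfg is not None:
        payload["config"] = asdict(cfg)
    return json.dumps(payload, indent=1)


def patterns_from_json(text: str) -> tuple[list[Pattern], TaskConfig | None]:
    payload = json.loads(text)
    pats = [
        Pattern(
            spikes=tuple((int(ch), float(t)) for ch, t in d["spikes"]),
            t_offset=d["t_offset"],
            t_duration=d["t_duration"],
            rewarded=d["rewarded"],
        )
        for d in payload["patterns"]
    ]
    cfg = TaskConfig(**payload["config"]) if "config" in payload else None
    return pats, cfg
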