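"""Pair-based STDP, non-associative reward-LTP and bounded weights.

The corticostriatal synapse model combines two mechanisms:

* **Pair-based all-to-all STDP.** Every pre/post spike pair contributes
  ``Φ(Δt)`` with ``Δt = t_post - t_pre``::

      Φ(Δt) = A_post_pre · exp(Δt / τ_s)    (Δt < 0)
              A_pre_post · exp(-Δt / τ_s)   (Δt > 0)
              0                             (Δt = 0)

  On a postsynaptic spike each channel's weight moves by ε times the sum
  of Φ over all of that channel's prior presynaptic spikes; on a
  presynaptic spike the channel moves by ε times the sum over all prior
  postsynaptic spikes. The four polarity presets are named after the
  field's terminology: symmetric LTD, asymmetric Hebbian, asymmetric
  anti-Hebbian, symmetric LTP.

* **Reward-LTP.** During a rewarded trial every presynaptic spike adds
  the non-associative potentiation ``ΔW = ε · A_reward`` to its channel,
  independent of postsynaptic activity.

Weights are clipped to ``[w_min, w_max]`` after every individual update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "STDPRule",
    "RewardRule",
    "WeightVector",
    "SpikeHistory",
    "STDP_PRESETS",
    "stdp_kernel",
    "on_post_spike",
    "on_pre_spike",
    "reset_history",
    "init_weights",
]


@dataclass(frozen=True)
class STDPRule:
    """STDP polarity amplitudes, timescale and plasticity rate.

    ``A_post_pre`` weights post-before-pre pairings (Δt < 0) and
    ``A_pre_post`` pre-before-post pairings (Δt > 0); both are
    dimensionless. ``epsilon`` converts amplitudes to nA.
    """

    A_post_pre: float
    A_pre_post: float
    tau_stdp: float = 20.0
    epsilon: float = 0.02

    def __post_init__(self) -> None:
        if self.tau_stdp <= 0:
            raise ValueError("tau_stdp must be positive")


#: Named polarity presets, ordered (A_post_pre, A_pre_post).
STDP_PRESETS: dict[str, STDPRule] = {
    "symmetric-ltd": STDPRule(-1.0, -1.0),
    "hebbian": STDPRule(-1.0, +1.0),
    "anti-hebbian": STDPRule(+1.0, -1.0),
    "symmetric-ltp": STDPRule(+1.0, +1.0),
}


@dataclass(frozen=True)
class RewardRule:
    """Non-associative reward-LTP amplitude; 0 disables supervision.

    Task learning uses 0.9; the stationary Poisson-drive experiments
    use 0.5.
    """

    A_reward: float = 0.9

    def __post_init__(self) -> None:
        if self.A_reward < 0:
            raise ValueError("A_reward must be nonnegative")


@dataclass
class WeightVector:
    """Per-channel synaptic weights (nA) with hard bounds."""

    w: np.ndarray
    w_min: float = 0.0
    w_max: float = 2.0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")

    def clip(self) -> None:
        np.clip(self.w, self.w_min, self.w_max, out=self.w)

    def copy(self) -> "WeightVector":
        return WeightVector(self.w.copy(), self.w_min, self.w_max)


def init_weights(
    P: int,
    rng: np.random.Generator,
    low: float = 0.0,
    high: float = 0.05,
    w_min: float = 0.0,
    w_max: float = 2.0,
) -> WeightVector:
    """Initial weights drawn uniformly at random in [low, high] nA."""
    return WeightVector(rng.uniform(low, high, size=P), w_min, w_max)


@dataclass
class SpikeHistory:
    """Trial-scoped pre/post spike times for all-to-all pairing."""

    pre: list[list[float]] = field(default_factory=list)
    post: list[float] = field(default_factory=list)

    @classmethod
    def empty(cls, P: int) -> "SpikeHistory":
        return cls(pre=[[] for _ in range(P)], post=[])

    def record_pre(self, channel: int, t: float) -> None:
        self.pre[channel - 1].append(t)

    def record_post(self, t: float) -> None:
        self.post.append(t)


def stdp_kernel(delta_t: float, rule: STDPRule) -> float:
    """Evaluate Φ(Δt); Φ(0) = 0 by convention."""
    if delta_t < 0:
        return rule.A_post_pre * math.exp(delta_t / rule.tau_stdp)
    if delta_t > 0:
        return rule.A_pre_post * math.exp(-delta_t / rule.tau_stdp)
    return 0.0


def on_post_spike(
    weights: WeightVector,
    hist: SpikeHistory,
    t_post: float,
    rule: STDPRule,
    record: bool = True,
) -> WeightVector:
    """Apply the postsynaptic-spike STDP update and clip.

    Each channel i moves by ``ε Σ_{t_pre,i < t_post} Φ(t_post - t_pre,i)``.
    The spike is appended to the history unless ``record=False``.
    """
    for i, pres in enumerate(hist.pre):
        s = sum(stdp_kernel(t_post - tp, rule) for tp in pres if tp < t_post)
        weights.w[i] += rule.epsilon * s
    weights.clip()
    if record:
        hist.record_post(t_post)
    return weights


def on_pre_spike(
    weights: WeightVector,
    hist: SpikeHistory,
    channel: int,
    t_pre: float,
    rule: STDPRule,
    reward: RewardRule | None = None,
    rewarded_trial: bool = False,
    record: bool = True,
) -> WeightVector:
    """Apply the presynaptic-spike STDP update (plus reward-LTP) and clip.

    Channel weight moves by ``ε Σ_{t_post < t_pre} Φ(t_post - t_pre)``,
    plus ``ε A_reward`` when the trial is rewarded.
    """
    s = sum(stdp_kernel(tp - t_pre, rule) for tp in hist.post if tp < t_pre)
    dw = rule.epsilon * s
    if rewarded_trial and reward is not None:
        dw += rule.epsilon * reward.A_reward
    weights.w[channel - 1] += dw
    weights.clip()
    if record:
        hist.record_pre(channel, t_pre)
    return weights


def reset_history(hist: SpikeHistory) -> SpikeHistory:
    """Clear all stored spike times (idempotent); trial-boundary reset."""
    for pres in hist.pre:
        pres.clear()
    hist.post.clear()
    return hist
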