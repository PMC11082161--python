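"""Accuracy measures and the closed-form error-mode theory.

The per-session classification accuracy over ``N_p`` patterns is

    Accuracy = (1/N_p) Σ_k  r_k σ_k + (1 - r_k)(1 - ν_k)

where ``r_k`` flags a rewarded pattern, ``ν_k`` whether the MSN spiked
at all during the trial and ``σ_k`` whether its first spike fell
strictly after the last template spike. MaxAccuracy is the sliding
maximum of the accuracy over ±T_1 test sessions; it smooths the
success/failure alternation intrinsic to the anti-Hebbian equilibrium.

The theory operations analyse the repeated presentation of a single
rewarded n-spike pattern to an M1 neuron:

* ``theory_Tp`` — the depression/potentiation boundary: channels
  spiking less than ``T_p = τ_s log(-A_pre_post / A_reward)`` ms before
  the pattern end are net-depressed on a success, earlier ones
  net-potentiated.
* ``max_successes`` — between two type-2 errors the system supports at
  most ``N = ceil(A_reward / |A_pre_post + A_reward|)`` successes, so
  the stationary accuracy cannot exceed ``1 - 1/N``.
* ``type1_necessary`` / ``type2_sufficient`` — voltage-sum conditions
  for premature spiking (type 1) and guaranteed silence (type 2),
  evaluated with the maximal per-spike voltage jump ``w_max`` (mV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "accuracy",
    "max_accuracy",
    "session_observables",
    "theory_Tp",
    "max_successes",
    "TheoryInputs",
    "type1_necessary",
    "type2_sufficient",
    "weight_to_jump",
]


def accuracy(outcomes: Sequence) -> float:
    """Mean of ``r σ + (1-r)(1-ν)`` over one outcome per pattern."""
    if len(outcomes) == 0:
        raise ValueError("accuracy of an empty outcome list is undefined")
    total = 0.0
    for o in outcomes:
        r = 1.0 if o.rewarded else 0.0
        total += r * o.sigma + (1.0 - r) * (1.0 - o.nu)
    return total / len(outcomes)


def max_accuracy(series: Sequence[float], T_1: int = 10) -> np.ndarray:
    """Sliding-window maximum over ±T_1 sessions, truncated at the ends."""
    if T_1 < 0:
        raise ValueError("T_1 must be nonnegative")
    a = np.asarray(series, dtype=float)
    out = np.empty_like(a)
    n = len(a)
    for i in range(n):
        out[i] = a[max(0, i - T_1) : min(n, i + T_1 + 1)].max()
    return out


def session_observables(
    first_spike_times: Sequence[float | None], pattern_end: float
) -> tuple[float, float | None]:
    """Across-repetition summary of one presentation index.

    Returns ``(P(no spike), mean first-spike time relative to the
    pattern end among spiking repetitions)``; the relative timing is
    None when every repetition stayed silent.
    """
    n = len(first_spike_times)
    if n == 0:
        raise ValueError("no repetitions supplied")
    silent = sum(1 for t in first_spike_times if t is None)
    p_none = silent / n
    spiking = [t - pattern_end for t in first_spike_times if t is not None]
    rel = float(np.mean(spiking)) if spiking else None
    return p_none, rel


def theory_Tp(tau_stdp: float, A_pre_post: float, A_reward: float) -> float:
    """Potentiation/depression boundary ``τ_s log(-A_pre_post/A_reward)`` (ms)."""
    if A_reward == 0:
        raise ValueError("T_p is undefined for A_reward = 0")
    ratio = -A_pre_post / A_reward
    if ratio <= 0:
        raise ValueError("T_p requires A_pre_post < 0 < A_reward")
    return tau_stdp * math.log(ratio)


def max_successes(A_reward: float, A_pre_post: float) -> tuple[int, float]:
    """Success ceiling ``N = ceil(A_reward/|A_pre_post + A_reward|)``.

    Returns ``(N, 1 - 1/N)``: N bounds the run of successes between two
    type-2 errors, hence 1/N bounds the stationary type-2 frequency and
    1 - 1/N the accuracy. Raises for the balanced case
    ``A_pre_post + A_reward = 0`` where the ceiling is unbounded.
    """
    denom = abs(A_pre_post + A_reward)
    if denom == 0:
        raise ValueError("A_pre_post + A_reward = 0: success run is unbounded")
    ratio = A_reward / denom
    # guard the ceiling against float error in near-integer ratios (0.9/0.1)
    N = math.ceil(ratio - 1e-9 * max(1.0, abs(ratio)))
    return N, 1.0 - 1.0 / N


@dataclass(frozen=True)
class TheoryInputs:
    """Inputs of the voltage-sum error conditions.

    ``spike_times`` are the template times t_1 < … < t_n (ms); ``w_max``
    is the maximal per-spike voltage jump in mV (convert a current bound
    with :func:`weight_to_jump`); ``V_r``, ``V_th``, ``tau`` come from
    the M1 parameters. ``baseline`` selects the reset (printed form) or
    resting potential as the summation baseline.
    """

    spike_times: tuple[float, ...]
    w_max: float
    V_r: float
    V_th: float
    tau: float
    baseline: str = "V_r"
    V_eq: float | None = None

    def _base(self) -> float:
        if self.baseline == "V_r":
            return self.V_r
        if self.baseline == "V_eq":
            if self.V_eq is None:
                raise ValueError("V_eq baseline requested but V_eq not given")
            return self.V_eq
        raise ValueError("baseline must be 'V_r' or 'V_eq'")


def weight_to_jump(w_nA: float, R: float) -> float:
    """Convert a synaptic-weight bound (nA) to a voltage jump (mV)."""
    return R * w_nA


def type1_necessary(inputs: TheoryInputs) -> bool:
    """Necessary condition for a premature (type-1) spike.

    True when the maximal voltage reachable at the (n-1)-th spike with
    all weights at their bound meets threshold:
    ``base + w_max Σ_{k=1}^{n-1} exp(-δ_k^{n-1}/τ) >= V_th``.
    """
    t = inputs.spike_times
    n = len(t)
    if n < 2:
        raise ValueError("type-1 condition needs at least two spikes")
    s = sum(math.exp(-(t[n - 2] - t[k]) / inputs.tau) for k in range(n - 1))
    return inputs._base() + inputs.w_max * s >= inputs.V_th


def type2_sufficient(inputs: TheoryInputs) -> bool:
    """Sufficient condition for systematic silence (type-2 errors).

    True when even the full pattern at maximal weights stays below
    threshold: ``base + w_max Σ_{k=1}^{n} exp(-δ_k^n/τ) <= V_th``.
    """
    t = inputs.spike_times
    n = len(t)
    if n < 1:
        raise ValueError("type-2 condition needs at least one spike")
    s = sum(math.exp(-(t[n - 1] - t[k]) / inputs.tau) for k in range(n))
    return inputs._base() + inputs.w_max * s <= inputs.V_th
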