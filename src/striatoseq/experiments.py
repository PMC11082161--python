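"""Headline experiment drivers used by the reproduction script and tests.

Each driver reconstructs one published observable from scratch:

* :func:`stationary_type2_percent` — stationary type-2 error frequency of
  the repeated single-pattern experiment, measured in the serrated
  (non-saturated) regime. The weight-ceiling axis is scanned as in the
  error-mode heatmap; cells where both error modes occur and successes
  dominate form the alternation regime, and the median type-2 frequency
  across those cells is reported.
* :func:`stationary_rates` — median MSN output rates under 10 Hz Poisson
  drive for the named plasticity conditions (5 s runs).
* :func:`timescale_sweep` — mean final accuracy of M2/alpha-synapse
  sequence learning across synaptic timescales, and the accuracy-
  maximizing timescale. Sequences use a 5 ms inter-spike delay and
  N_p = 10 patterns so that the sequence span falls inside the tested
  timescale range (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neurons import M1Params, M2Params, SynapseKernel
from .patterns import TaskConfig, gen_task1
from .plasticity import STDP_PRESETS, RewardRule
from .protocol import (
    NetworkConfig,
    TrainConfig,
    run_single_pattern_experiment,
    run_stationary_poisson,
    run_training,
)

__all__ = [
    "stationary_type2_percent",
    "stationary_rates",
    "RATE_CONDITIONS",
    "timescale_sweep",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class ErrorModeScan:
    """Per-cell error frequencies and the serrated-regime summary."""

    w_grid: np.ndarray
    success: np.ndarray
    type1: np.ndarray
    type2: np.ndarray
    serrated_mask: np.ndarray
    type2_percent: float


def stationary_type2_percent(
    seed: int,
    pattern_duration: float = 20.0,
    w_grid: np.ndarray | None = None,
    burn_in: int = 300,
    scored: int = 500,
) -> ErrorModeScan:
    """Median stationary type-2 % across alternation-regime cells.

    A cell qualifies as serrated when both error types occur and
    successes are the majority outcome — the regime where the
    success-run ceiling N bounds the type-2 frequency.
    """
    if w_grid is None:
        w_grid = np.arange(0.150, 0.2001, 0.002)
    succ = np.empty(len(w_grid))
    t1 = np.empty(len(w_grid))
    t2 = np.empty(len(w_grid))
    for i, wm in enumerate(w_grid):
        res = run_single_pattern_experiment(
            pattern_duration=pattern_duration,
            w_max=float(wm),
            n_presentations=burn_in + scored,
            rng=_rng(seed, 2, i),
        )
        succ[i], t1[i], t2[i] = res.stationary_freqs(burn_in)
    mask = (t1 > 0) & (t2 > 0) & (succ >= 0.5)
    value = float(np.median(t2[mask]) * 100.0) if mask.any() else float("nan")
    return ErrorModeScan(w_grid, succ, t1, t2, mask, value)


#: Fig-2a-style stationary conditions: preset, A_reward, weight init.
RATE_CONDITIONS = {
    "symmetric-ltd+reward": ("symmetric-ltd", 0.5, (0.0, 0.05)),
    "anti-hebbian+reward": ("anti-hebbian", 0.5, (0.0, 0.05)),
    "symmetric-ltp": ("symmetric-ltp", 0.0, (0.0, 2.0)),
    "symmetric-ltd": ("symmetric-ltd", 0.0, (0.0, 0.05)),
}


def stationary_rates(
    seed: int,
    conditions: dict | None = None,
    rate_hz: float = 10.0,
    n_reps: int = 20,
    duration_s: float = 5.0,
) -> dict[str, float]:
    """Median output rate (Hz) per plasticity condition, P = 10 channels."""
    conditions = RATE_CONDITIONS if conditions is None else conditions
    out = {}
    for i, (name, (preset, A, init)) in enumerate(conditions.items()):
        res = run_stationary_poisson(
            M1Params(),
            STDP_PRESETS[preset],
            A_reward=A,
            rate_hz=rate_hz,
            P=10,
            duration_s=duration_s,
            n_reps=n_reps,
            rng=_rng(seed, 3, i),
            w_init=init,
        )
        out[name] = res.median_rate_hz
    return out


TIMESCALE_GRID = (0.5, 1.0, 3.0, 5.0, 10.0, 15.0)


def timescale_sweep(
    seed: int,
    grid: tuple[float, ...] = TIMESCALE_GRID,
    n_reps: int = 24,
    N_p: int = 10,
    t_delay: float = 5.0,
    n_iterations: int = 500,
) -> tuple[dict[float, np.ndarray], float]:
    """Final accuracy per alpha-synapse timescale and the grid argmax.

    M2 neuron, asymmetric anti-Hebbian STDP, reward 0.9, fixed-delay
    sequences. Returns (per-timescale accuracy arrays, best timescale).
    """
    task = TaskConfig(P=10, N_p=N_p, N_stim=3, t_delay=t_delay)
    train = TrainConfig(n_iterations=n_iterations)
    cells: dict[float, np.ndarray] = {}
    for i, T_s in enumerate(grid):
        accs = []
        for rep in range(n_reps):
            rng = _rng(seed, 6, i, rep)
            patterns = gen_task1(task, rng)
            net = NetworkConfig(
                model=M2Params(), kernel=SynapseKernel("alpha", T_s)
            )
            res = run_training(
                patterns, task, net, STDP_PRESETS["anti-hebbian"],
                RewardRule(0.9), train, rng,
            )
            accs.append(res.final_accuracy)
        cells[T_s] = np.asarray(accs)
    means = {k: float(v.mean()) for k, v in cells.items()}
    best = max(means, key=means.get)
    return cells, float(best)
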