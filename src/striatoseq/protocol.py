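"""Training/test orchestration for one- and two-MSN circuits.

A *trial* presents one pattern for ``t_duration`` ms: membrane state and
spike histories start fresh, plasticity (STDP + reward-LTP on rewarded
patterns) acts on the weight vector, and the weights carry over to the
next trial. Every ``test_every`` training iterations a *test session*
presents each pattern once with weights frozen and all noise off, and
the classification verdicts feed the accuracy series.

A rewarded pattern counts as a success only when the MSN's first spike
falls strictly after the last template spike (σ = 1); firing earlier is
a type-1 error, not firing at all a type-2 error. A non-rewarded
pattern is correct iff the MSN stays silent.

Two-MSN mode adds collateral inhibition: MSN₂ integrates the same
cortical input through its own weights and each of its spikes injects
an instantaneous ``R·J`` mV (J ≤ 0) jump into MSN₁, whose verdicts alone
define accuracy. Under the differential reward scheme MSN₂ is rewarded
exactly on MSN₁'s non-rewarded patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from . import _engine
from .metrics import accuracy as eq3_accuracy
from .metrics import max_accuracy
from .neurons import InputSpec, M1Params, M2Params, SynapseKernel
from .patterns import Pattern, TaskConfig, add_noise_spikes, jitter_pattern, subpatterns
from .plasticity import RewardRule, STDPRule, STDP_PRESETS

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "TrialOutcome",
    "TrainingResult",
    "classify_trial",
    "run_trial",
    "run_two_msn_trial",
    "run_training",
    "run_stationary_poisson",
    "StationaryResult",
    "run_single_pattern_experiment",
    "run_error_mode_grid",
    "SinglePatternResult",
    "subpattern_silence",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Circuit layout: MSN model, synapse kernel, and inhibition."""

    model: M1Params | M2Params = M1Params()
    kernel: SynapseKernel = SynapseKernel("dirac")
    n_msn: int = 1
    J: float = -0.5
    reward_scheme: Literal["differential", "same"] = "differential"
    w_init: tuple[float, float] = (0.0, 0.05)
    w_min: float = 0.0
    w_max: float = 2.0
    v_noise: bool = True

    def __post_init__(self) -> None:
        if self.n_msn not in (1, 2):
            raise ValueError("n_msn must be 1 or 2")
        if self.J > 0:
            raise ValueError("collateral weight J must be <= 0")


@dataclass(frozen=True)
class TrainConfig:
    """Training-loop sizes; ``test_every`` defaults to N_p."""

    n_iterations: int = 500
    test_every: int | None = None
    T_1: int = 10
    n_repetitions: int = 250
    dt: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_iterations", "T_1", "n_repetitions"):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class TrialOutcome:
    """Per-trial verdict: spike flags, first-spike time and error type."""

    pattern_id: int
    rewarded: bool
    nu: int
    sigma: int
    first_spike: float | None
    error: Literal["success", "type1", "type2", "n/a"]


def classify_trial(
    pattern: Pattern, spike_times: Sequence[float], pattern_id: int = 0
) -> TrialOutcome:
    """Verdict of one presentation from the MSN spike train.

    ν = 1 iff any spike occurred within the trial; σ = 1 iff the first
    spike is strictly later than the last template spike.
    """
    spikes = [t for t in spike_times if 0.0 <= t <= pattern.t_duration]
    nu = 1 if spikes else 0
    first = min(spikes) if spikes else None
    sigma = 1 if (first is not None and first > pattern.last_spike_time) else 0
    if pattern.rewarded:
        error = "success" if sigma else ("type1" if nu else "type2")
    else:
        error = "n/a"
    return TrialOutcome(pattern_id, pattern.rewarded, nu, sigma, first, error)


def _reward_flags(pattern: Pattern, net: NetworkConfig) -> tuple[bool, ...]:
    if net.n_msn == 1:
        return (pattern.rewarded,)
    if net.reward_scheme == "differential":
        return (pattern.rewarded, not pattern.rewarded)
    return (pattern.rewarded, pattern.rewarded)


def run_trial(
    pattern: Pattern,
    net: NetworkConfig,
    weights: np.ndarray,
    stdp: STDPRule | None,
    reward: RewardRule | None,
    task: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
    dt: float = 0.1,
    with_noise: bool = True,
) -> tuple[TrialOutcome, list[np.ndarray]]:
    """One presentation; mutates ``weights`` when ``stdp`` is given.

    ``weights`` has shape (n_msn, P). With ``with_noise`` the trial
    carries the task's Poisson background and membrane noise; test
    sessions call this with ``with_noise=False`` and ``stdp=None``.
    """
    if with_noise and task is not None:
        inputs = add_noise_spikes(pattern, task, rng, v_noise=net.v_noise)
    else:
        inputs = InputSpec(cortical=pattern.spikes, v_noise=with_noise and net.v_noise)
    events = _engine.build_events([inputs], dt, pattern.t_duration)[0]
    res = _engine.run(
        model=net.model,
        kernel=net.kernel,
        weights=weights,
        events=events,
        duration=pattern.t_duration,
        dt=dt,
        w_ext=inputs.w_ext,
        J=net.J if net.n_msn == 2 else 0.0,
        stdp=stdp,
        reward_amp=0.0 if reward is None else reward.A_reward,
        w_bounds=(net.w_min, net.w_max),
        rewarded=_reward_flags(pattern, net),
        v_noise=inputs.v_noise,
        rng=rng,
    )
    outcome = classify_trial(pattern, res.spike_times[0])
    return outcome, res.spike_times


def run_two_msn_trial(
    pattern: Pattern,
    net: NetworkConfig,
    weights: np.ndarray,
    stdp: STDPRule | None,
    reward: RewardRule | None,
    rng: np.random.Generator | None = None,
    dt: float = 0.1,
) -> tuple[TrialOutcome, list[np.ndarray]]:
    """Noise-free two-MSN presentation; accuracy is read on MSN₁ only."""
    if net.n_msn != 2:
        raise ValueError("run_two_msn_trial requires n_msn = 2")
    return run_trial(
        pattern, net, weights, stdp, reward, rng=rng, dt=dt, with_noise=False
    )


@dataclass
class TrainingResult:
    """Accuracy trajectory, outcome log and weight history of one run."""

    session_iteration: np.ndarray
    accuracy: np.ndarray
    max_accuracy: np.ndarray
    outcomes: list[list[TrialOutcome]]
    weights_sessions: np.ndarray
    final_weights: np.ndarray

    @property
    def final_accuracy(self) -> float:
        return float(self.accuracy[-1])

    @property
    def final_max_accuracy(self) -> float:
        return float(self.max_accuracy[-1])


def run_training(
    patterns: Sequence[Pattern],
    task: TaskConfig,
    net: NetworkConfig,
    stdp: STDPRule,
    reward: RewardRule,
    train: TrainConfig,
    rng: np.random.Generator,
) -> TrainingResult:
    """Full training run with interleaved frozen-weight test sessions.

    Patterns are drawn uniformly with replacement; rewarded ones engage
    reward-LTP. Weights start uniform in ``net.w_init``. Test sessions
    present every pattern once, noise-free and plasticity-free.
    """
    P = task.P
    n_p = len(patterns)
    if n_p == 0:
        raise ValueError("empty pattern set")
    test_every = train.test_every or n_p
    weights = rng.uniform(net.w_init[0], net.w_init[1], size=(net.n_msn, P))

    session_it: list[int] = []
    acc: list[float] = []
    outcomes_log: list[list[TrialOutcome]] = []
    weights_sessions: list[np.ndarray] = []

    for it in range(train.n_iterations):
        p = patterns[int(rng.integers(n_p))]
        if task.tau_pattern > 0:
            p = jitter_pattern(p, task.tau_pattern, rng)
        run_trial(
            p, net, weights, stdp, reward, task=task, rng=rng, dt=train.dt,
            with_noise=True,
        )
        if (it + 1) % test_every == 0:
            outcomes = []
            for pid, pat in enumerate(patterns):
                o, _ = run_trial(
                    pat, net, weights, stdp=None, reward=None, dt=train.dt,
                    with_noise=False,
                )
                outcomes.append(replace(o, pattern_id=pid))
            session_it.append(it + 1)
            acc.append(eq3_accuracy(outcomes))
            outcomes_log.append(outcomes)
            weights_sessions.append(weights.copy())

    acc_arr = np.asarray(acc)
    return TrainingResult(
        session_iteration=np.asarray(session_it),
        accuracy=acc_arr,
        max_accuracy=max_accuracy(acc_arr, train.T_1),
        outcomes=outcomes_log,
        weights_sessions=np.asarray(weights_sessions),
        final_weights=weights,
    )


@dataclass
class StationaryResult:
    """Stationary Poisson-drive statistics across repetitions."""

    rates_hz: np.ndarray
    median_rate_hz: float
    final_weights: np.ndarray
    weight_rec: list[np.ndarray]


def run_stationary_poisson(
    model: M1Params | M2Params,
    stdp: STDPRule,
    A_reward: float,
    rate_hz: float,
    P: int = 10,
    duration_s: float = 5.0,
    n_reps: int = 20,
    rng: np.random.Generator | None = None,
    w_init: tuple[float, float] = (0.0, 0.05),
    w_bounds: tuple[float, float] = (0.0, 2.0),
    dt: float = 0.1,
    kernel: SynapseKernel = SynapseKernel("dirac"),
    w_rec_every_ms: float | None = None,
) -> StationaryResult:
    """Uninterrupted runs under independent Poisson drive on P channels.

    Plasticity (and reward-LTP when ``A_reward > 0``) acts continuously;
    spike histories span the whole run. Returns per-repetition output
    rates and their median.
    """
    rng = np.random.default_rng() if rng is None else rng
    duration = duration_s * 1000.0
    rates = np.empty(n_reps)
    finals = np.empty((n_reps, P))
    recs: list[np.ndarray] = []
    for rep in range(n_reps):
        ev_t = []
        ev_c = []
        for ch in range(1, P + 1):
            n = rng.poisson(rate_hz / 1000.0 * duration)
            ev_t.append(rng.uniform(0.0, duration, size=n))
            ev_c.append(np.full(n, ch))
        times = np.concatenate(ev_t)
        chans = np.concatenate(ev_c).astype(int)
        spec = InputSpec(
            cortical=tuple(zip(chans.tolist(), times.tolist())), v_noise=True
        )
        events = _engine.build_events([spec], dt, duration)[0]
        weights = rng.uniform(w_init[0], w_init[1], size=(1, P))
        res = _engine.run(
            model=model,
            kernel=kernel,
            weights=weights,
            events=events,
            duration=duration,
            dt=dt,
            stdp=stdp,
            reward_amp=A_reward,
            w_bounds=w_bounds,
            rewarded=(A_reward > 0,),
            v_noise=True,
            rng=rng,
            w_rec_every=int(round(w_rec_every_ms / dt)) if w_rec_every_ms else 0,
        )
        rates[rep] = len(res.spike_times[0]) / duration_s
        finals[rep] = weights[0]
        if res.weight_rec is not None:
            recs.append(res.weight_rec)
    return StationaryResult(
        rates_hz=rates,
        median_rate_hz=float(np.median(rates)),
        final_weights=finals,
        weight_rec=recs,
    )


@dataclass
class SinglePatternResult:
    """Outcome labels and weight trace of a repeated-pattern experiment."""

    labels: list[str]
    weight_trace: np.ndarray
    accuracy: float
    type1_freq: float
    type2_freq: float

    def stationary_freqs(self, burn_in: int) -> tuple[float, float, float]:
        lab = self.labels[burn_in:]
        n = max(len(lab), 1)
        return (
            sum(l == "success" for l in lab) / n,
            sum(l == "type1" for l in lab) / n,
            sum(l == "type2" for l in lab) / n,
        )


def run_single_pattern_experiment(
    pattern_duration: float = 20.0,
    w_max: float = 2.0,
    n_presentations: int = 200,
    n_spikes: int = 4,
    P: int = 10,
    model: M1Params | None = None,
    stdp: STDPRule | None = None,
    A_reward: float = 0.9,
    t_offset: float = 10.0,
    rng: np.random.Generator | None = None,
    dt: float = 0.1,
) -> SinglePatternResult:
    """Repeated presentation of one rewarded fixed-interval pattern.

    The pattern has ``n_spikes`` spikes on channels 1..n_spikes with a
    constant inter-spike interval spanning ``pattern_duration`` ms. No
    noise of any kind; weights start uniform in [0, 0.05] nA (the rng
    seeds only this draw) and evolve across presentations while the
    membrane and histories reset between presentations.
    """
    model = M1Params(eta_noise=0.0) if model is None else model
    stdp = STDP_PRESETS["anti-hebbian"] if stdp is None else stdp
    rng = np.random.default_rng() if rng is None else rng
    delay = pattern_duration / (n_spikes - 1)
    spikes = tuple((k + 1, t_offset + k * delay) for k in range(n_spikes))
    t_duration = t_offset + pattern_duration + 30.0
    pattern = Pattern(spikes, t_offset, t_duration, rewarded=True)
    events = _engine.build_events(
        [InputSpec(cortical=pattern.spikes)], dt, t_duration
    )[0]
    weights = rng.uniform(0.0, 0.05, size=(1, P))
    labels: list[str] = []
    trace = np.empty((n_presentations, P))
    for k in range(n_presentations):
        res = _engine.run(
            model=model,
            kernel=SynapseKernel("dirac"),
            weights=weights,
            events=events,
            duration=t_duration,
            dt=dt,
            stdp=stdp,
            reward_amp=A_reward,
            w_bounds=(0.0, w_max),
            rewarded=(True,),
        )
        labels.append(classify_trial(pattern, res.spike_times[0]).error)
        trace[k] = weights[0]
    n = len(labels)
    return SinglePatternResult(
        labels=labels,
        weight_trace=trace,
        accuracy=sum(l == "success" for l in labels) / n,
        type1_freq=sum(l == "type1" for l in labels) / n,
        type2_freq=sum(l == "type2" for l in labels) / n,
    )


def run_error_mode_grid(
    durations: Sequence[float],
    w_maxes: Sequence[float],
    n_presentations: int = 200,
    seed: int = 0,
    **kwargs,
) -> list[dict]:
    """Sweep (pattern duration × weight bound) cells; one row per cell."""
    rows = []
    for d in durations:
        for wm in w_maxes:
            res = run_single_pattern_experiment(
                pattern_duration=d,
                w_max=wm,
                n_presentations=n_presentations,
                rng=np.random.default_rng(seed),
                **kwargs,
            )
            rows.append(
                {
                    "duration_ms": d,
                    "w_max_nA": wm,
                    "accuracy": res.accuracy,
                    "type1_freq": res.type1_freq,
                    "type2_freq": res.type2_freq,
                }
            )
    return rows


def subpattern_silence(
    patterns: Sequence[Pattern],
    net: NetworkConfig,
    weights: np.ndarray,
    rng: np.random.Generator,
    n_draws: int = 5,
    dt: float = 0.1,
) -> float:
    """Fraction of random proper subpatterns that elicit no spike.

    Only rewarded patterns with at least two spikes are probed (a
    trained network should treat their partial sequences as unlearned
    stimuli and stay silent).
    """
    probes = [p for p in patterns if p.rewarded and len(p.spikes) >= 2]
    if not probes:
        raise ValueError("no rewarded multi-spike pattern to probe")
    silent = 0
    total = 0
    for p in probes:
        for _ in range(n_draws):
            sub = subpatterns(p, rng)
            o, _ = run_trial(
                sub, net, weights, stdp=None, reward=None, dt=dt, with_noise=False
            )
            silent += 1 - o.nu
            total += 1
    return silent / total
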