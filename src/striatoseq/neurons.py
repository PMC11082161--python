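"""Medium spiny neuron (MSN) membrane models and synaptic current kernels.

Two point-neuron models of the striatal output neuron are provided:

* **M1** — a leaky integrate-and-fire neuron,
  ``tau dV/dt = -(V - V_eq) + R I(t) + sqrt(tau) V_noise(t)``,
  with parameters fitted to whole-cell recordings of MSNs in mouse
  dorsolateral striatum. Spikes are emitted when ``V`` crosses ``V_th``;
  the voltage is reset to ``V_r`` and spike emission is suppressed for an
  absolute refractory period.

* **M2** — an adaptive quadratic (Izhikevich-type) neuron,
  ``C dV/dt = k (V - V_c)(V - V_eq) - U + I`` coupled to the adaptation
  variable ``dU/dt = a (b (V - V_eq) - U)``, in the parameter regime that
  reproduces the MSN's hallmark spike latency: near-rheobase inputs place
  the voltage just past the unstable point ``V_c`` and the spike takes
  several milliseconds to develop.

Cortical input arrives as weighted spike events. With Dirac synapses each
presynaptic spike of weight ``W`` (nA) produces an instantaneous voltage
jump of ``R W`` mV (``R_scale W`` for M2); with exponential or alpha
synapses the same total charge is spread over a postsynaptic-current
kernel of unit time-integral (see :func:`psc_kernel_value`).

Units throughout: mV, ms, nA, MΩ, nF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "M1Params",
    "M2Params",
    "SynapseKernel",
    "NeuronState",
    "InputSpec",
    "TABLE_M1_FITTED",
    "TABLE_M2",
    "psc_kernel_value",
    "exact_m1_between_events",
    "step_m1",
    "step_m2",
    "simulate_trial",
    "TrialResult",
]


@dataclass(frozen=True)
class M1Params:
    """Leaky integrate-and-fire MSN parameters (model M1).

    Defaults are the values fitted to n=16 patch-clamp recordings.
    ``eta_noise`` is the membrane-noise amplitude in mV: the per-step
    Euler voltage increment has standard deviation ``eta_noise * sqrt(dt)``.
    """

    V_eq: float = -76.72
    V_th: float = -39.51
    V_r: float = -41.70
    R: float = 118.50
    tau: float = 11.85
    tau_refractory: float = 10.0
    eta_noise: float = 0.5

    def __post_init__(self) -> None:
        if not (self.V_eq < self.V_th):
            raise ValueError("M1Params requires V_eq < V_th")
        if not (self.V_r < self.V_th):
            raise ValueError("M1Params requires V_r < V_th")
        if self.R <= 0 or self.tau <= 0:
            raise ValueError("M1Params requires R > 0 and tau > 0")
        if self.tau_refractory < 0:
            raise ValueError("M1Params requires tau_refractory >= 0")

    @property
    def rheobase(self) -> float:
        """Minimal constant current (nA) whose steady state reaches V_th."""
        return (self.V_th - self.V_eq) / self.R


@dataclass(frozen=True)
class M2Params:
    """Adaptive quadratic MSN parameters (model M2).

    Voltage/adaptation defaults follow the canonical MSN parameterisation
    of the Izhikevich model family; ``k`` is in nA/mV^2 (0.001 nA/mV^2 =
    1 pA/mV^2) and ``V_c`` is the instability threshold above which the
    quadratic term drives a regenerative spike upstroke. ``R_scale`` is
    the scaling resistance (MΩ) multiplying synaptic currents so that a
    Dirac spike of weight W produces an ``R_scale * W`` mV jump.
    ``tau_I`` (ms) is the current-scaling time constant carried by the
    synaptic input-current definition (it keeps weights on the scale of
    measured EPSCs): with continuous kernels a spike of weight W
    contributes ``R_scale * tau_I * W * φ(t)`` to dV/dt, while Dirac
    spikes follow the jump convention above.
    """

    C: float = 0.05
    k: float = 0.001
    V_c: float = -25.0
    V_eq: float = -80.0
    V_th: float = -20.0
    V_r: float = -55.0
    a: float = 0.01
    b: float = -0.02
    d: float = 0.15
    R_scale: float = 100.0
    tau_I: float = 11.85
    eta_noise: float = 0.5

    def __post_init__(self) -> None:
        if self.C <= 0 or self.a <= 0:
            raise ValueError("M2Params requires C > 0 and a > 0")
        if not (self.V_eq < self.V_c < self.V_th):
            raise ValueError("M2Params requires V_eq < V_c < V_th")


#: Table of fitted M1 constants (aliases of the dataclass defaults).
TABLE_M1_FITTED = M1Params()
#: Adaptive quadratic MSN constants.
TABLE_M2 = M2Params()


@dataclass(frozen=True)
class SynapseKernel:
    """Postsynaptic-current shape: ``dirac``, ``exponential`` or ``alpha``.

    For the continuous kinds the kernel integrates to one over [0, inf),
    so a spike of weight W always injects the same total charge
    irrespective of the timescale ``T_s`` (ms).
    """

    kind: Literal["dirac", "exponential", "alpha"] = "dirac"
    T_s: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("dirac", "exponential", "alpha"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind != "dirac" and self.T_s <= 0:
            raise ValueError("T_s must be positive for continuous kernels")


def psc_kernel_value(kernel: SynapseKernel, t: float) -> float:
    """Evaluate the normalized postsynaptic-current kernel at time t (ms).

    Returns ``exp(-t/T_s)/T_s`` for exponential synapses and
    ``t exp(-t/T_s)/T_s^2`` for alpha synapses; 0 for t < 0. The Dirac
    kernel has no pointwise density and raises ``ValueError``.
    """
    if kernel.kind == "dirac":
        raise ValueError("Dirac kernel has no pointwise density")
    if t < 0:
        return 0.0
    if kernel.kind == "exponential":
        return math.exp(-t / kernel.T_s) / kernel.T_s
    return t * math.exp(-t / kernel.T_s) / kernel.T_s**2


@dataclass
class NeuronState:
    """Mutable integration state of a single MSN.

    ``syn`` holds the per-kernel synaptic state (aggregated over channels):
    empty for Dirac, ``[g]`` for exponential, ``[g, h]`` for alpha where
    ``h`` feeds the rising phase.
    """

    V: float
    U: float = 0.0
    refractory_until: float = -math.inf
    syn: list[float] = field(default_factory=list)


@dataclass
class InputSpec:
    """Realized input events of one trial.

    ``cortical``: sequence of (channel, time_ms) with channels in 1..P;
    ``external``: spike times of the unweighted external drive (weight
    ``w_ext`` nA each); ``v_noise`` toggles the membrane white noise.
    """

    cortical: Sequence[tuple[int, float]] = ()
    external: Sequence[float] = ()
    w_ext: float = 1.0
    v_noise: bool = False

    def validate(self, P: int, duration: float) -> None:
        for ch, t in self.cortical:
            if not (1 <= ch <= P):
                raise ValueError(f"channel {ch} outside 1..{P}")
            if not (0.0 <= t <= duration):
                raise ValueError(f"cortical spike time {t} outside trial")
        for t in self.external:
            if not (0.0 <= t <= duration):
                raise ValueError(f"external spike time {t} outside trial")


def exact_m1_between_events(
    p: M1Params, V0: float, I_const: float, delta_t: float
) -> float:
    """Closed-form noise-free M1 voltage after ``delta_t`` ms.

    Solves ``tau dV/dt = -(V - V_eq) + R I_const`` exactly:
    ``V_inf + (V0 - V_inf) exp(-delta_t/tau)`` with
    ``V_inf = V_eq + R I_const``. Serves as the event-driven oracle for
    the Euler integrator.
    """
    v_inf = p.V_eq + p.R * I_const
    return v_inf + (V0 - v_inf) * math.exp(-delta_t / p.tau)


def _syn_drive(kernel: SynapseKernel, state: NeuronState) -> float:
    if kernel.kind == "exponential":
        return state.syn[0]
    if kernel.kind == "alpha":
        return state.syn[0]
    return 0.0


def _syn_decay(kernel: SynapseKernel, state: NeuronState, dt: float) -> None:
    if kernel.kind == "exponential":
        state.syn[0] *= math.exp(-dt / kernel.T_s)
    elif kernel.kind == "alpha":
        g, h = state.syn
        # two-state cascade: g' = -g/T_s + h, h' = -h/T_s (forward Euler)
        state.syn[0] = g + dt * (-g / kernel.T_s + h)
        state.syn[1] = h + dt * (-h / kernel.T_s)


def _syn_kick(kernel: SynapseKernel, state: NeuronState, w: float) -> None:
    if kernel.kind == "exponential":
        state.syn[0] += w / kernel.T_s
    elif kernel.kind == "alpha":
        state.syn[1] += w / kernel.T_s**2


def new_state(model: M1Params | M2Params, kernel: SynapseKernel) -> NeuronState:
    n_syn = {"dirac": 0, "exponential": 1, "alpha": 2}[kernel.kind]
    return NeuronState(V=model.V_eq, U=0.0, syn=[0.0] * n_syn)


def step_m1(
    state: NeuronState,
    p: M1Params,
    kernel: SynapseKernel,
    dirac_jump: float,
    t: float,
    dt: float,
    noise: float = 0.0,
    I_const: float = 0.0,
) -> bool:
    """Advance an M1 state by one Euler step over [t, t+dt).

    ``dirac_jump`` is the summed instantaneous voltage jump (mV) of the
    Dirac events landing in this step (R-scaled by the caller);
    ``noise`` is a standard-normal draw (ignored when ``eta_noise`` is 0).
    Returns True when a spike is emitted, stamped at t+dt. During the
    refractory period the membrane keeps integrating but emission is
    suppressed.
    """
    V = state.V + dirac_jump
    drive = p.R * _syn_drive(kernel, state)
    _syn_decay(kernel, state, dt)
    V += dt * (-(V - p.V_eq) + p.R * I_const) / p.tau + dt * drive
    V += p.eta_noise * math.sqrt(dt) * noise
    t_spike = t + dt
    if V >= p.V_th and t_spike > state.refractory_until:
        state.V = p.V_r
        state.refractory_until = t_spike + p.tau_refractory
        return True
    state.V = V
    return False


def step_m2(
    state: NeuronState,
    p: M2Params,
    kernel: SynapseKernel,
    dirac_jump: float,
    t: float,
    dt: float,
    noise: float = 0.0,
    I_const: float = 0.0,
) -> bool:
    """Advance an M2 state by one Euler step over [t, t+dt).

    Spikes are detected on the upward crossing of ``V_th`` (or numeric
    blow-up of the quadratic term); the voltage is reset to ``V_r`` and
    the adaptation variable jumps by ``d``. No refractory period.
    """
    V = state.V + dirac_jump
    drive = p.R_scale * p.tau_I * _syn_drive(kernel, state)
    _syn_decay(kernel, state, dt)
    dV = dt * ((p.k * (V - p.V_c) * (V - p.V_eq) - state.U + I_const) / p.C + drive)
    dU = dt * p.a * (p.b * (V - p.V_eq) - state.U)
    V = V + dV
    state.U += dU
    if p.eta_noise > 0.0:
        V += p.eta_noise * math.sqrt(dt) * noise
    if V >= p.V_th or not math.isfinite(V):
        state.V = p.V_r
        state.U += p.d
        return True
    state.V = V
    return False


@dataclass
class TrialResult:
    """Output of :func:`simulate_trial`."""

    spike_times: np.ndarray
    v_trace: np.ndarray
    t: np.ndarray


def simulate_trial(
    model: M1Params | M2Params,
    kernel: SynapseKernel,
    inputs: InputSpec,
    weights: Sequence[float],
    duration: float,
    dt: float = 0.1,
    rng: np.random.Generator | None = None,
) -> TrialResult:
    """Euler-scheme simulation of one trial from rest; plasticity frozen.

    Cortical spikes on channel i are weighted by ``weights[i-1]``; the
    voltage trace is sampled at the end of every step. Deterministic
    given the rng when membrane noise is on, and rng-independent when
    off.
    """
    from . import _engine

    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise ValueError("weight vector must not be empty")
    if duration <= 0:
        raise ValueError("duration must be positive")
    inputs.validate(len(weights), duration)
    res = _engine.run(
        model=model,
        kernel=kernel,
        weights=weights[None, :].copy(),
        events=_engine.build_events([inputs], dt, duration)[0],
        duration=duration,
        dt=dt,
        w_ext=inputs.w_ext,
        v_noise=inputs.v_noise,
        rng=rng,
        record_v=True,
    )
    n_steps = int(round(duration / dt))
    t = (np.arange(n_steps) + 1) * dt
    return TrialResult(spike_times=res.spike_times[0], v_trace=res.v_trace[0], t=t)
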