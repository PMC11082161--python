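"""Slow, readable reference implementation of the trial dynamics.

This mirrors the semantics of the compiled core in :mod:`._engine`
step-for-step — same event ordering, spike-time stamping, refractory
handling and plasticity conventions — but is written in plain Python on
top of the public plasticity operations (:func:`on_pre_spike`,
:func:`on_post_spike`). The test suite asserts that both paths produce
identical spike trains and weights on randomized inputs; experiments
always use the compiled core.
"""

from __future__ import annotations

import math

import numpy as np

from .neurons import M1Params, M2Params, SynapseKernel
from .plasticity import (
    RewardRule,
    STDPRule,
    SpikeHistory,
    WeightVector,
    on_post_spike,
    on_pre_spike,
)

__all__ = ["run_reference"]


def run_reference(
    model: M1Params | M2Params,
    kernel: SynapseKernel,
    weights: np.ndarray,
    events: tuple[np.ndarray, np.ndarray],
    duration: float,
    dt: float = 0.1,
    w_ext: float = 1.0,
    J: float = 0.0,
    stdp: STDPRule | None = None,
    reward_amp: float = 0.0,
    w_bounds: tuple[float, float] = (0.0, 2.0),
    rewarded: tuple[bool, ...] = (False,),
    noise: np.ndarray | None = None,
    i_const: float = 0.0,
    i_const_duration: float | None = None,
):
    """Run the reference integrator; returns (spike_times, v_trace, W)."""
    W = np.array(weights, dtype=float)
    n_neurons, P = W.shape
    n_steps = int(round(duration / dt))
    ev_step, ev_chan = events
    is_m1 = isinstance(model, M1Params)
    Rm = model.R if is_m1 else model.R_scale
    drive_mult = model.R if is_m1 else model.R_scale * model.tau_I
    wv = [WeightVector(W[n], w_bounds[0], w_bounds[1]) for n in range(n_neurons)]
    hist = [SpikeHistory.empty(P) for _ in range(n_neurons)]
    reward = RewardRule(reward_amp) if stdp is not None else None

    V = np.full(n_neurons, model.V_eq)
    U = np.zeros(n_neurons)
    g = np.zeros(n_neurons)
    h = np.zeros(n_neurons)
    ref_until = np.full(n_neurons, -np.inf)
    v_trace = np.zeros((n_neurons, n_steps))
    spikes: list[list[float]] = [[] for _ in range(n_neurons)]
    i_const_steps = (
        n_steps if i_const_duration is None else int(round(i_const_duration / dt))
    )

    ie = 0
    for k in range(n_steps):
        t = k * dt
        jump = np.zeros(n_neurons)
        while ie < len(ev_step) and ev_step[ie] == k:
            ch = int(ev_chan[ie])
            if ch >= 0:
                for n in range(n_neurons):
                    w_cur = wv[n].w[ch]
                    if kernel.kind == "dirac":
                        jump[n] += Rm * w_cur
                    elif kernel.kind == "exponential":
                        g[n] += w_cur / kernel.T_s
                    else:
                        h[n] += w_cur / kernel.T_s**2
                    if stdp is not None:
                        on_pre_spike(
                            wv[n], hist[n], ch + 1, t, stdp, reward, rewarded[n]
                        )
            else:
                for n in range(n_neurons):
                    if kernel.kind == "dirac":
                        jump[n] += Rm * w_ext
                    elif kernel.kind == "exponential":
                        g[n] += w_ext / kernel.T_s
                    else:
                        h[n] += w_ext / kernel.T_s**2
            ie += 1
        Ic = i_const if k < i_const_steps else 0.0
        t_spike = t + dt
        inhib = 0.0
        for n in reversed(range(n_neurons)):
            v = V[n] + jump[n]
            drv = drive_mult * g[n]
            if is_m1:
                v = v + dt * (-(v - model.V_eq) + Rm * Ic) / model.tau + dt * drv
            else:
                dv = dt * (
                    (model.k * (v - model.V_c) * (v - model.V_eq) - U[n] + Ic)
                    / model.C
                    + drv
                )
                U[n] += dt * model.a * (model.b * (v - model.V_eq) - U[n])
                v = v + dv
            if noise is not None and model.eta_noise > 0:
                v += model.eta_noise * math.sqrt(dt) * noise[n, k]
            if n == 0:
                v += inhib
            crossed = v >= model.V_th or not math.isfinite(v)
            can_fire = (not is_m1) or t_spike > ref_until[n]
            if crossed and can_fire:
                V[n] = model.V_r
                if is_m1:
                    ref_until[n] = t_spike + model.tau_refractory
                else:
                    U[n] += model.d
                spikes[n].append(t_spike)
                if stdp is not None:
                    on_post_spike(wv[n], hist[n], t_spike, stdp)
                else:
                    hist[n].record_post(t_spike)
                if n == 1:
                    inhib += Rm * J
            else:
                V[n] = v
            v_trace[n, k] = V[n]
        if kernel.kind == "exponential":
            g *= math.exp(-dt / kernel.T_s)
        elif kernel.kind == "alpha":
            g, h = g + dt * (-g / kernel.T_s + h), h + dt * (-h / kernel.T_s)

    return [np.asarray(s) for s in spikes], v_trace, W
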