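"""Compiled Euler-scheme core for one- and two-MSN trials.

This module is an implementation detail: the public surface lives in
:mod:`striatoseq.neurons`, :mod:`striatoseq.plasticity` and
:mod:`striatoseq.protocol`. The core integrates one or two MSNs (models
M1/M2, Dirac/exponential/alpha synapses) with optional pair-based STDP
and reward-LTP applied event-by-event, using exact all-to-all history
sums for the STDP updates (the same sums as the reference operations in
:mod:`striatoseq.plasticity`, asserted equal in the test suite).

Conventions (shared with the pure-Python reference):

* input events are applied at the left edge of their Euler step;
* output spikes are stamped at the right edge (t + dt) of the step in
  which threshold is crossed, so a Dirac-triggered spike pairs with its
  triggering presynaptic spike at Δt = dt on the pre-post branch;
* exactly coincident pre/post times contribute Φ(0) = 0;
* the presynaptic current uses the weight value in force immediately
  before that spike's own plasticity update;
* in two-MSN mode, a spike of MSN₂ injects an R·J mV jump into MSN₁
  within the same step, before MSN₁'s threshold test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .neurons import InputSpec, M1Params, M2Params, SynapseKernel

_M1, _M2 = 0, 1
_KERNEL_ID = {"dirac": 0, "exponential": 1, "alpha": 2}


@njit(cache=False)
def _core(
    model_kind,
    P,
    Veq,
    Vth,
    Vr,
    Rm,
    drive_mult,
    tau,
    tau_ref,
    Cm,
    kq,
    Vc,
    a_ad,
    b_ad,
    d_ad,
    kernel_kind,
    T_s,
    n_steps,
    dt,
    ev_step,
    ev_chan,
    n_neurons,
    W,
    w_ext,
    J,
    plast_on,
    A_post_pre,
    A_pre_post,
    tau_s,
    eps,
    A_reward,
    rewarded,
    w_min,
    w_max,
    noise_amp,
    noise,
    i_const,
    i_const_steps,
    record_v,
    V_out,
    w_rec_every,
    W_rec,
    pre_times,
    pre_counts,
    post_times,
    post_counts,
):
    V = np.empty(n_neurons)
    U = np.zeros(n_neurons)
    g = np.zeros(n_neurons)
    h = np.zeros(n_neurons)
    ref_until = np.empty(n_neurons)
    for n in range(n_neurons):
        V[n] = Veq
        ref_until[n] = -1.0e18
    jump = np.zeros(n_neurons)
    ie = 0
    n_ev = ev_step.shape[0]
    use_noise = noise_amp > 0.0 and noise.shape[1] > 0
    sqdt = math.sqrt(dt)
    n_rec = 0
    for kstep in range(n_steps):
        t = kstep * dt
        for n in range(n_neurons):
            jump[n] = 0.0
        while ie < n_ev and ev_step[ie] == kstep:
            ch = ev_chan[ie]
            if ch >= 0:
                for n in range(n_neurons):
                    w_cur = W[n, ch]
                    if kernel_kind == 0:
                        jump[n] += Rm * w_cur
                    elif kernel_kind == 1:
                        g[n] += w_cur / T_s
                    else:
                        h[n] += w_cur / (T_s * T_s)
                    if plast_on:
                        s = 0.0
                        for j in range(post_counts[n]):
                            dtt = post_times[n, j] - t
                            if dtt < 0.0:
                                s += A_post_pre * math.exp(dtt / tau_s)
                        dw = eps * s
                        if rewarded[n] == 1:
                            dw += eps * A_reward
                        w_new = w_cur + dw
                        if w_new < w_min:
                            w_new = w_min
                        elif w_new > w_max:
                            w_new = w_max
                        W[n, ch] = w_new
                pre_times[ch, pre_counts[ch]] = t
                pre_counts[ch] += 1
            else:
                for n in range(n_neurons):
                    if kernel_kind == 0:
                        jump[n] += Rm * w_ext
                    elif kernel_kind == 1:
                        g[n] += w_ext / T_s
                    else:
                        h[n] += w_ext / (T_s * T_s)
            ie += 1
        Ic = i_const if kstep < i_const_steps else 0.0
        t_spike = t + dt
        inhib = 0.0
        for idx in range(n_neurons):
            n = n_neurons - 1 - idx  # inhibitor (index 1) integrates first
            v = V[n] + jump[n]
            drv = drive_mult * g[n]
            if model_kind == _M1:
                v = v + dt * (-(v - Veq) + Rm * Ic) / tau + dt * drv
            else:
                dv = dt * ((kq * (v - Vc) * (v - Veq) - U[n] + Ic) / Cm + drv)
                du = dt * a_ad * (b_ad * (v - Veq) - U[n])
                v = v + dv
                U[n] += du
            if use_noise:
                v += noise_amp * sqdt * noise[n, kstep]
            if n == 0:
                v += inhib
            spiked = False
            if v >= Vth or not math.isfinite(v):
                if model_kind == _M2 or t_spike > ref_until[n]:
                    spiked = True
            if spiked:
                V[n] = Vr
                if model_kind == _M2:
                    U[n] += d_ad
                else:
                    ref_until[n] = t_spike + tau_ref
                post_times[n, post_counts[n]] = t_spike
                post_counts[n] += 1
                if plast_on:
                    for i in range(P):
                        s = 0.0
                        for j in range(pre_counts[i]):
                            dtt = t_spike - pre_times[i, j]
                            if dtt > 0.0:
                                s += A_pre_post * math.exp(-dtt / tau_s)
                        w_new = W[n, i] + eps * s
                        if w_new < w_min:
                            w_new = w_min
                        elif w_new > w_max:
                            w_new = w_max
                        W[n, i] = w_new
                if n == 1:
                    inhib += Rm * J
            else:
                V[n] = v
            if record_v:
                V_out[n, kstep] = V[n]
        if kernel_kind == 1:
            dec = math.exp(-dt / T_s)
            for n in range(n_neurons):
                g[n] *= dec
        elif kernel_kind == 2:
            for n in range(n_neurons):
                gn = g[n]
                hn = h[n]
                g[n] = gn + dt * (-gn / T_s + hn)
                h[n] = hn + dt * (-hn / T_s)
        if w_rec_every > 0 and (kstep + 1) % w_rec_every == 0:
            for i in range(P):
                W_rec[n_rec, i] = W[0, i]
            n_rec += 1
    return 0


@dataclass
class EngineResult:
    """Spike times (per neuron), optional traces, and final weights."""

    spike_times: list
    v_trace: np.ndarray | None
    weights: np.ndarray
    weight_rec: np.ndarray | None


def build_events(
    input_specs: Sequence[InputSpec], dt: float, duration: float
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Convert InputSpecs to sorted (step, channel) event arrays.

    Channels become 0-based; external spikes get channel -1. Events at
    t = duration land in the final step.
    """
    n_steps = int(round(duration / dt))
    out = []
    for spec in input_specs:
        steps = []
        chans = []
        for ch, t in spec.cortical:
            steps.append(min(int(math.floor(t / dt + 1e-9)), n_steps - 1))
            chans.append(ch - 1)
        for t in spec.external:
            steps.append(min(int(math.floor(t / dt + 1e-9)), n_steps - 1))
            chans.append(-1)
        ev_step = np.asarray(steps, dtype=np.int64)
        ev_chan = np.asarray(chans, dtype=np.int64)
        order = np.argsort(ev_step, kind="stable")
        out.append((ev_step[order], ev_chan[order]))
    return out


def run(
    model: M1Params | M2Params,
    kernel: SynapseKernel,
    weights: np.ndarray,
    events: tuple[np.ndarray, np.ndarray],
    duration: float,
    dt: float = 0.1,
    w_ext: float = 1.0,
    J: float = 0.0,
    stdp=None,
    reward_amp: float = 0.0,
    w_bounds: tuple[float, float] = (0.0, 2.0),
    rewarded: Sequence[bool] = (False,),
    v_noise: bool = False,
    rng: np.random.Generator | None = None,
    record_v: bool = False,
    i_const: float = 0.0,
    i_const_duration: float | None = None,
    w_rec_every: int = 0,
) -> EngineResult:
    """Run the compiled core once. ``weights`` (n_neurons, P) is mutated
    in place when plasticity is active."""
    weights = np.ascontiguousarray(weights, dtype=np.float64)
    n_neurons, P = weights.shape
    n_steps = int(round(duration / dt))
    ev_step, ev_chan = events

    if isinstance(model, M1Params):
        model_kind = _M1
        args_m1 = (
            model.V_eq, model.V_th, model.V_r, model.R, model.R,
            model.tau, model.tau_refractory,
        )
        args_m2 = (1.0, 0.0, 0.0, 1.0, 0.0, 0.0)
        eta = model.eta_noise
    else:
        model_kind = _M2
        args_m1 = (
            model.V_eq, model.V_th, model.V_r, model.R_scale,
            model.R_scale * model.tau_I, 1.0, 0.0,
        )
        args_m2 = (model.C, model.k, model.V_c, model.a, model.b, model.d)
        eta = model.eta_noise

    if stdp is not None:
        plast_on = True
        A_pp, A_pr, tau_s, eps = stdp.A_post_pre, stdp.A_pre_post, stdp.tau_stdp, stdp.epsilon
        w_min, w_max = w_bounds
    else:
        plast_on = False
        A_pp = A_pr = 0.0
        tau_s, eps, reward_amp = 20.0, 0.0, 0.0
        w_min, w_max = 0.0, np.inf

    rewarded_arr = np.zeros(n_neurons, dtype=np.int8)
    for n, r in enumerate(rewarded[:n_neurons]):
        rewarded_arr[n] = 1 if r else 0

    if v_noise and eta > 0.0:
        if rng is None:
            raise ValueError("rng required when membrane noise is enabled")
        noise = rng.standard_normal((n_neurons, n_steps))
        noise_amp = eta
    else:
        noise = np.zeros((n_neurons, 0))
        noise_amp = 0.0

    V_out = np.zeros((n_neurons, n_steps)) if record_v else np.zeros((n_neurons, 0))
    n_rec = n_steps // w_rec_every if w_rec_every > 0 else 0
    W_rec = np.zeros((max(n_rec, 1), P)) if w_rec_every > 0 else np.zeros((1, P))

    per_chan = np.bincount(ev_chan[ev_chan >= 0], minlength=P) if ev_chan.size else np.zeros(P, int)
    pre_cap = int(per_chan.max()) + 1 if per_chan.size else 1
    pre_times = np.zeros((P, pre_cap))
    pre_counts = np.zeros(P, dtype=np.int64)
    post_times = np.zeros((n_neurons, n_steps + 1))
    post_counts = np.zeros(n_neurons, dtype=np.int64)

    i_const_steps = n_steps if i_const_duration is None else int(round(i_const_duration / dt))

    _core(
        model_kind,
        P,
        *args_m1,
        *args_m2,
        _KERNEL_ID[kernel.kind],
        float(kernel.T_s),
        n_steps,
        float(dt),
        ev_step,
        ev_chan,
        n_neurons,
        weights,
        float(w_ext),
        float(J),
        plast_on,
        float(A_pp),
        float(A_pr),
        float(tau_s),
        float(eps),
        float(reward_amp),
        rewarded_arr,
        float(w_min),
        float(w_max),
        float(noise_amp),
        noise,
        float(i_const),
        i_const_steps,
        record_v,
        V_out,
        int(w_rec_every),
        W_rec,
        pre_times,
        pre_counts,
        post_times,
        post_counts,
    )

    spike_times = [post_times[n, : post_counts[n]].copy() for n in range(n_neurons)]
    return EngineResult(
        spike_times=spike_times,
        v_trace=V_out if record_v else None,
        weights=weights,
        weight_rec=W_rec[:n_rec] if w_rec_every > 0 else None,
    )
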