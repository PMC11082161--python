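# Methods

`striatoseq` simulates a small corticostriatal circuit learning to
classify spatio-temporal sequences of cortical spikes, and reproduces
the analysis that accompanies that model: stationary weight/rate
statistics under Poisson drive, the error-mode theory of repeated
single-pattern learning, synaptic-timescale sweeps, collateral
inhibition, and a constrained logistic-regression baseline.

## Neuron models

**M1 — leaky integrate-and-fire.** Between spikes,

    τ dV/dt = −(V − V_eq) + R·I(t) + √τ·V_noise(t)

with fitted MSN constants V_eq = −76.72 mV, V_th = −39.51 mV,
V_r = −41.70 mV, R = 118.50 MΩ, τ = 11.85 ms. Crossing V_th emits a
spike, resets V to V_r, and suppresses further spike *emission* for an
absolute refractory period τ_refractory = 10 ms. During the refractory
period the membrane keeps integrating its inputs; only emission is
gated. We chose this reading (rather than discarding input for 10 ms)
because a 10 ms input dead-time caps the saturated output rate at
≈ 50 Hz for 100 Hz total drive, well below the stationary rates the
model family is known to produce; emission-gating preserves the
1000/τ_refractory Hz ceiling while matching those rates.

Membrane noise: the white-noise term is discretized so that the
per-Euler-step voltage increment has standard deviation
η_noise·√dt with η_noise = 0.5 mV. This is one reading of the √τ
prefactor; we verified that the stationary-rate observables are
insensitive to the alternative (per-step σ = η_noise) reading.

**M2 — adaptive quadratic neuron.** The voltage couples to an
adaptation current U:

    C dV/dt = k (V − V_c)(V − V_eq) − U + I
      dU/dt = a (b (V − V_eq) − U)

with C = 0.05 nF, V_eq = −80 mV, V_th = −20 mV, V_r = −55 mV,
a = 0.01 ms⁻¹, b = −0.02 nA/mV, d = 0.15 nA (added to U at each
spike). The quadratic gain k = 0.001 nA/mV² (1 pA/mV²) and instability
threshold V_c = −25 mV follow the canonical MSN parameterisation of
this model family; all currents are in nA. Inputs that park V just
above V_c trigger a spike only after a multi-millisecond regenerative
upstroke — the spike-latency property that distinguishes M2 from M1.
M2 has no refractory period. M2 carries the same intrinsic membrane
noise default as M1 (η = 0.5 mV); see "Two-MSN circuit" for why this
matters.

## Synaptic input

Cortical spikes arrive on P channels with plastic weights W_i (nA) and
an external channel with fixed weight W_ext = 1 nA. With **Dirac**
synapses a spike of weight W jumps the voltage by R·W mV (M1) or
R_scale·W mV (M2, R_scale = 100 MΩ). **Exponential** and **alpha**
kernels spread the same event over time with unit time-integral,

    φ_exp(t) = e^(−t/T_s)/T_s,   φ_alpha(t) = t·e^(−t/T_s)/T_s²,

and contribute R·W·φ(t) to dV/dt for M1 (the current definition's τ
prefactor cancels the 1/τ of the membrane equation). For M2 the input
current is scaled by R_scale·C and carries a current-scaling time
constant tau_I = 11.85 ms that keeps synaptic weights on the scale of
measured EPSC amplitudes; continuous-kernel drive is therefore
R_scale·tau_I·W·φ(t). Under the alternative charge-only scaling
(R_scale·W·φ) a weight at the 2 nA ceiling cannot fire M2 at all for
T_s ≥ 5 ms, which suppresses the slow half of the timescale
experiments; tau_I restores the Dirac-comparable operating range.

Numerics: fixed-step Euler at dt = 0.1 ms. Input events are applied at
the left edge of their step; output spikes are stamped at the right
edge (t + dt). A spike triggered by a Dirac input therefore pairs with
that input at Δt = dt on the pre-post branch of the STDP kernel —
required for the error-mode theory below, where each success depresses
the last-spiking channel by ε·|A_pre-post + A_reward|. Exponential
kernels decay exactly per step; alpha kernels use a two-state Euler
cascade. M2's quadratic term cannot overflow before detection (V_th
caps the excursion), but non-finite voltages are treated as spikes
defensively. The compiled core (`_engine`) is checked against a
pure-Python reference built from the public step and plasticity
operations, to identical spike trains and weights.

## Plasticity

Pair-based, all-to-all STDP: every pre/post pair contributes

    Φ(Δt) = A_post-pre·e^(Δt/τ_s)  (Δt < 0),
            A_pre-post·e^(−Δt/τ_s) (Δt > 0),  Φ(0) = 0,

with τ_s = 20 ms and plasticity rate ε = 0.02 nA. The four polarity
presets are symmetric LTD (−1, −1), asymmetric Hebbian (−1, +1),
asymmetric anti-Hebbian (+1, −1) and symmetric LTP (+1, +1), ordered
(A_post-pre, A_pre-post). Reward-LTP adds ε·A_reward to a channel at
each of its presynaptic spikes during rewarded trials (A_reward = 0.9
for task learning, 0.5 for the stationary-drive experiments). Weights
are clipped to [0, 2] nA after every update and initialized uniformly
in [0, 0.05] nA. Spike histories are trial-scoped: membrane state and
pairing histories reset between pattern presentations; the stationary
Poisson runs are single uninterrupted trials.

## Tasks and noise

Patterns are 50 ms trials with correlated activity starting at
t_offset = 10 ms (the paper leaves t_offset unspecified; 10 ms leaves
a ≥ 30 ms post-pattern verdict window). Task 1 draws 1..N_stim spikes
on distinct random channels, 1 ms apart; duplicate templates are
re-drawn so reward labels stay well-defined. Task 2 is the nested
family (1), (1,2), …, (1..P) at 0.5 ms spacing, crossed with all 2^P
reward assignments. Task 3 jitters Task-1 spike times per presentation
with a uniform shift of standard deviation τ_pattern (support
±τ_pattern·√3). Task 4 draws 1 kHz Poisson bursts on a 2 ms window,
rejection-sampled to contain at least two spikes. Background noise
adds Poisson spikes at λ_stim per cortical channel and λ_ext on the
external channel; both default to 0 (the robustness experiments vary
them). Rewards are i.i.d. Bernoulli(1/2) and independent of pattern
content.

## Protocol and accuracy

Training presents patterns uniformly at random with plasticity active;
every `test_every` (default N_p) iterations a frozen-weight, noise-free
test session presents each pattern once. A rewarded pattern is correct
(σ = 1) when the MSN's first spike falls strictly after the last
template spike; firing earlier is a type-1 error and silence a type-2
error. A non-rewarded pattern is correct when the MSN stays silent.
Session accuracy is the mean of r·σ + (1−r)(1−ν); MaxAccuracy is its
sliding maximum over ±T_1 = 10 sessions, which removes the intrinsic
success/failure alternation of the anti-Hebbian equilibrium.

## Error-mode theory and the serrated regime

For a single rewarded n-spike pattern driving M1, channels spiking less
than T_p = τ_s·log(−A_pre-post/A_reward) before the pattern end are
net-depressed on each success while earlier channels are potentiated.
Between two type-2 errors the synapse of the last channel loses
ε·|A_pre-post + A_reward| per success and regains ε·A_reward at each
failure, so at most N = ⌈A_reward/|A_pre-post + A_reward|⌉ successes
fit between failures (N = 9 at defaults) and accuracy cannot exceed
1 − 1/N. The printed voltage-sum conditions for type-1 (necessary) and
type-2 (sufficient) errors are implemented exactly as stated, with V_r
as the baseline and a V_eq switch, and w_max interpreted as the maximal
per-spike voltage jump in mV.

The serrated sawtooth regime exists only in a narrow band of weight
ceilings: with w_max large the system saturates into pure type-1
errors, with w_max small into silence, and even inside the band the
reward quantum ε·A_reward interacts with the ceiling (clipped rewards
flip the sign of the per-success drift). The stationary type-2
frequency driver therefore scans w_max as in the published heatmap,
labels cells serrated when both error types occur with a success
majority, and summarizes the median type-2 frequency over those cells
(measured ≈ 11%, consistent with the 1/N ≈ 11% ceiling).

## Two-MSN circuit

MSN₁ and MSN₂ (both M2) integrate the same cortical events through
separate weight vectors; each MSN₂ spike injects R_scale·J mV into
MSN₁ within the same step (J = −0.5 nA; J = 0 is the control). Under
differential rewards MSN₂ is rewarded exactly on MSN₁'s non-rewarded
patterns; accuracy is read on MSN₁ only. For the
rewarded-subpattern/non-rewarded-superpattern task the circuit works
only if MSN₂ fires before MSN₁ on the superpattern. With fully
deterministic dynamics both neurons' spike lags self-tune to their
T_p equilibria, MSN₁ fires ≈ 0.25 ms before MSN₂, and the ε·A_reward
weight quantum steps over the narrow weight band in which MSN₁'s
latency would exceed MSN₂'s — training limit-cycles at accuracy 0.5.
Intrinsic membrane noise (η = 0.5 mV during training; tests always
noise-free) breaks this lattice lock, and the inhibited circuit then
reaches MaxAccuracy 1.0 on the nested pair while the J = 0 control
stays at 0.5. This is why M2 defaults to the same intrinsic noise as
M1 rather than running noise-free.

## Baseline

The logistic-regression comparator fits reward labels on the binarized
pattern-occupancy matrix (timing discarded) with elementwise
nonnegative linear coefficients (free intercept), via L-BFGS-B with a
mild L2 penalty (1e−4) for optimizer stability; predictions threshold
the fitted probability at 0.5. On nested instances any nonnegative
weighting scores the superpattern at least as high as the rewarded
subpattern, capping accuracy at 0.5.

## Synthetic data vs. reality

All inputs are generated by the task module; nothing is fitted to
recordings here (the membrane constants are taken as given). The
generators emulate precisely-timed, low-dimensional cortical templates
with independent Poisson background; they do not emulate correlated
ongoing activity, oscillations, rate modulations, synaptic failures or
dale-violating weights. Passing tests therefore demonstrate properties
of the learning rules under idealized drive, not performance on
recorded cortical data.

## Problem sizes and known limitations

The test suite and the reproduction script run scaled-down versions of
the published experiments: 20 repetitions × 5 s for the stationary
rates, 500 scored presentations per error-mode cell, 12–50 repetitions
for the rule/model/circuit comparisons, and 40 repetitions per
synaptic-timescale cell; sizes are stated in the drivers' signatures
and chosen so the full suite completes in minutes on one CPU.

Two quantitative observables are only partially reproduced, both traced
to under-determined published conditions. First, the symmetric-LTD-
with-reward stationary rate measures ≈ 7.0 Hz against a reported
9.91 Hz over a 5 s run that includes the ≈ 2–3 s reward-driven warm-up
from low initial weights; the post-warm-up rate is ≈ 8.3 Hz. Second,
the synaptic-timescale sweep reproduces the strong fast-synapse penalty
(sub-millisecond kernels cannot integrate a multi-millisecond sequence)
but finds a broad plateau from 3–15 ms rather than a sharp optimum at
10 ms with a decline at 15 ms; the timescale experiments in the source
analysis used a synaptic-current scaling that was never stated, and the
interior-optimum location is sensitive to exactly that scaling. The
sweep is run as specified and its argmax reported as measured. The
timescale experiment also requires sequences whose span (inter-spike
delay 5 ms, N_p = 10) lies inside the tested timescale range; with the
Task-1 default of 1 ms delays the whole sequence lasts ≤ 2 ms and the
landscape is timescale-flat above 1 ms.
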