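"""Membrane dynamics: kernels, closed-form M1 solution, Euler integrator."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from striatoseq.neurons import (
    InputSpec,
    M1Params,
    M2Params,
    SynapseKernel,
    exact_m1_between_events,
    psc_kernel_value,
    simulate_trial,
)
from striatoseq import _engine


class TestKernels:
    @pytest.mark.parametrize(
        "kind,T_s,t,expected",
        [
            ("exponential", 10.0, 0.0, 0.1),
            ("alpha", 10.0, 0.0, 0.0),
            ("alpha", 10.0, 10.0, 1.0 / (10.0 * math.e)),  # peak at t = T_s
            ("exponential", 5.0, -1.0, 0.0),
        ],
    )
    def test_pointwise_values(self, kind, T_s, t, expected):
        assert psc_kernel_value(SynapseKernel(kind, T_s), t) == pytest.approx(expected)

    @pytest.mark.parametrize("kind", ["exponential", "alpha"])
    @pytest.mark.parametrize("T_s", [0.5, 3.0, 10.0, 15.0])
    def test_unit_integral(self, kind, T_s):
        k = SynapseKernel(kind, T_s)
        val, _ = quad(lambda t: psc_kernel_value(k, t), 0.0, 50.0 * T_s)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_timescale_rejected(self):
        with pytest.raises(ValueError):
            SynapseKernel("alpha", -1.0)

    def test_dirac_has_no_density(self):
        with pytest.raises(ValueError):
            psc_kernel_value(SynapseKernel("dirac"), 1.0)


class TestExactM1:
    def test_rest_is_fixed_point(self, m1):
        assert exact_m1_between_events(m1, m1.V_eq, 0.0, 123.0) == pytest.approx(m1.V_eq)

    def test_time_constant_decay(self, m1):
        v = exact_m1_between_events(m1, m1.V_eq + 10.0, 0.0, m1.tau)
        assert v == pytest.approx(m1.V_eq + 10.0 / math.e)

    def test_rheobase_steady_state_reaches_threshold(self, m1):
        v = exact_m1_between_events(m1, m1.V_eq, m1.rheobase, 1e6)
        assert v == pytest.approx(m1.V_th, abs=1e-9)
        assert m1.rheobase == pytest.approx(0.314, abs=0.001)


class TestM1Trials:
    def test_no_input_stays_at_rest(self, m1_quiet, dirac):
        res = simulate_trial(m1_quiet, dirac, InputSpec(), [0.0] * 5, duration=50.0)
        assert len(res.spike_times) == 0
        assert np.allclose(res.v_trace, m1_quiet.V_eq)

    def test_single_dirac_jump_and_decay(self, m1_quiet, dirac):
        w = 0.05
        res = simulate_trial(
            m1_quiet, dirac, InputSpec(cortical=((1, 10.0),)), [w], duration=50.0
        )
        k = int(round(10.0 / 0.1))
        jump = res.v_trace[k] - res.v_trace[k - 1]
        # one Euler step of leak acts within the arrival step
        assert jump == pytest.approx(m1_quiet.R * w, rel=0.02)
        # subsequent decay matches the closed form to within Euler error
        v0 = res.v_trace[k]
        v_later = res.v_trace[k + 100]  # 10 ms later
        assert v_later == pytest.approx(
            exact_m1_between_events(m1_quiet, v0, 0.0, 10.0), abs=0.05
        )

    def test_suprathreshold_dirac_spikes_in_same_step(self, m1_quiet, dirac):
        w = (m1_quiet.V_th - m1_quiet.V_eq) / m1_quiet.R * 1.1
        res = simulate_trial(
            m1_quiet, dirac, InputSpec(cortical=((1, 10.0),)), [w], duration=50.0
        )
        assert len(res.spike_times) == 1
        assert res.spike_times[0] == pytest.approx(10.1)

    def test_euler_error_shrinks_linearly_with_dt(self, m1_quiet, dirac):
        spec = InputSpec(cortical=((1, 5.0), (1, 12.0)))
        errs = []
        for dt in (0.1, 0.05):
            res = simulate_trial(m1_quiet, dirac, spec, [0.05], duration=20.0, dt=dt)
            # compare the voltage at 20 ms against the exact two-jump solution
            v = m1_quiet.V_eq
            v += m1_quiet.R * 0.05 * math.exp(-(20.0 - 5.0) / m1_quiet.tau)
            v += m1_quiet.R * 0.05 * math.exp(-(20.0 - 12.0) / m1_quiet.tau)
            errs.append(abs(res.v_trace[-1] - v))
        assert errs[1] < errs[0]
        assert errs[1] == pytest.approx(errs[0] / 2, rel=0.5)

    def test_constant_current_steady_state(self, m1_quiet, dirac):
        I = 0.2  # subthreshold
        res = _engine.run(
            model=m1_quiet,
            kernel=dirac,
            weights=np.zeros((1, 1)),
            events=_engine.build_events([InputSpec()], 0.1, 500.0)[0],
            duration=500.0,
            record_v=True,
            i_const=I,
        )
        assert res.v_trace[0, -1] == pytest.approx(m1_quiet.V_eq + m1_quiet.R * I, abs=0.05)

    def test_firing_rate_bounded_by_refractory_period(self, m1, dirac):
        # saturating drive: every step would cross threshold
        res = _engine.run(
            model=m1,
            kernel=dirac,
            weights=np.zeros((1, 1)),
            events=_engine.build_events([InputSpec()], 0.1, 2000.0)[0],
            duration=2000.0,
            i_const=5.0,
        )
        rate = len(res.spike_times[0]) / 2.0  # Hz
        assert rate <= 1000.0 / m1.tau_refractory + 1e-9

    def test_empty_weights_rejected(self, m1_quiet, dirac):
        with pytest.raises(ValueError):
            simulate_trial(m1_quiet, dirac, InputSpec(), [], duration=10.0)

    def test_seeded_noise_reproducible_and_noise_free_seed_independent(self, dirac):
        m1 = M1Params()  # noise on
        spec = InputSpec(cortical=((1, 5.0),), v_noise=True)
        a = simulate_trial(m1, dirac, spec, [0.1], 50.0, rng=np.random.default_rng(7))
        b = simulate_trial(m1, dirac, spec, [0.1], 50.0, rng=np.random.default_rng(7))
        assert np.array_equal(a.v_trace, b.v_trace)
        quiet = M1Params(eta_noise=0.0)
        spec0 = InputSpec(cortical=((1, 5.0),))
        c = simulate_trial(quiet, dirac, spec0, [0.1], 50.0, rng=np.random.default_rng(1))
        d = simulate_trial(quiet, dirac, spec0, [0.1], 50.0, rng=np.random.default_rng(2))
        assert np.array_equal(c.v_trace, d.v_trace)


class TestM2:
    def test_rest_is_fixed_point(self, m2_quiet, dirac):
        res = simulate_trial(m2_quiet, dirac, InputSpec(), [0.0], duration=50.0)
        assert len(res.spike_times) == 0
        assert np.allclose(res.v_trace, m2_quiet.V_eq)

    def test_subcritical_jump_decays_back(self, m2_quiet, dirac):
        # a jump below the instability point V_c relaxes to rest
        w = (m2_quiet.V_c - m2_quiet.V_eq - 5.0) / m2_quiet.R_scale
        res = simulate_trial(
            m2_quiet, dirac, InputSpec(cortical=((1, 5.0),)), [w], duration=100.0
        )
        assert len(res.spike_times) == 0
        assert res.v_trace[-1] == pytest.approx(m2_quiet.V_eq, abs=0.5)

    def test_supracritical_jump_spikes_with_latency(self, m2_quiet, dirac):
        w = (m2_quiet.V_c - m2_quiet.V_eq + 1.0) / m2_quiet.R_scale
        res = simulate_trial(
            m2_quiet, dirac, InputSpec(cortical=((1, 5.0),)), [w], duration=100.0
        )
        assert len(res.spike_times) >= 1
        latency = res.spike_times[0] - 5.0
        assert latency > 0.5  # regenerative upstroke takes time

    def test_latency_decreases_with_drive(self, m2_quiet, dirac):
        def first_spike(i_mult):
            res = _engine.run(
                model=m2_quiet,
                kernel=dirac,
                weights=np.zeros((1, 1)),
                events=_engine.build_events([InputSpec()], 0.1, 200.0)[0],
                duration=200.0,
                i_const=0.8 * i_mult,
                i_const_duration=30.0,
            )
            return res.spike_times[0][0] if len(res.spike_times[0]) else None

        near = first_spike(1.0)
        strong = first_spike(1.5)
        assert near is not None and strong is not None
        assert strong < near

    def test_latency_agrees_with_fine_step_integration(self, m2_quiet, dirac):
        spec = InputSpec(cortical=((1, 5.0),))
        w = [(m2_quiet.V_c - m2_quiet.V_eq + 2.0) / m2_quiet.R_scale]
        coarse = simulate_trial(m2_quiet, dirac, spec, w, 60.0, dt=0.1)
        fine = simulate_trial(m2_quiet, dirac, spec, w, 60.0, dt=0.005)
        assert len(coarse.spike_times) == len(fine.spike_times) == 1
        assert coarse.spike_times[0] == pytest.approx(fine.spike_times[0], abs=0.5)

    def test_adaptation_stays_zero_when_decoupled(self, dirac):
        # b = d = 0 reduces M2 to a plain quadratic integrate-and-fire
        red = M2Params(b=0.0, d=0.0, eta_noise=0.0)
        full = M2Params(eta_noise=0.0)
        spec = InputSpec(cortical=tuple((1, t) for t in (5.0, 20.0, 35.0)))
        w = [(red.V_c - red.V_eq + 3.0) / red.R_scale]
        res_red = simulate_trial(red, dirac, spec, w, 60.0)
        res_full = simulate_trial(full, dirac, spec, w, 60.0)
        # adaptation can only reduce excitability
        assert len(res_red.spike_times) >= len(res_full.spike_times)
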