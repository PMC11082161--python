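"""Trial verdicts, training-loop invariants and the experiment drivers."""

import numpy as np
import pytest

from striatoseq.neurons import M1Params, M2Params
from striatoseq.patterns import Pattern, TaskConfig, gen_task1
from striatoseq.plasticity import STDP_PRESETS, RewardRule
from striatoseq.protocol import (
    NetworkConfig,
    TrainConfig,
    classify_trial,
    run_single_pattern_experiment,
    run_stationary_poisson,
    run_training,
    run_trial,
    run_two_msn_trial,
)


class TestClassify:
    def setup_method(self):
        self.p_rew = Pattern(((1, 10.0), (2, 11.0)), rewarded=True)
        self.p_non = Pattern(((1, 10.0), (2, 11.0)), rewarded=False)

    def test_silent_rewarded_is_type2(self):
        o = classify_trial(self.p_rew, [])
        assert (o.nu, o.sigma, o.error) == (0, 0, "type2")

    def test_spike_after_pattern_is_success(self):
        o = classify_trial(self.p_rew, [12.0])
        assert (o.nu, o.sigma, o.error) == (1, 1, "success")

    def test_spike_during_pattern_is_type1(self):
        o = classify_trial(self.p_rew, [10.5])
        assert (o.nu, o.sigma, o.error) == (1, 0, "type1")

    def test_spike_at_last_template_time_not_after(self):
        o = classify_trial(self.p_rew, [11.0])
        assert o.sigma == 0  # strictly-later rule

    def test_non_rewarded_spike_flags_nu(self):
        o = classify_trial(self.p_non, [30.0])
        assert (o.nu, o.error) == (1, "n/a")

    def test_sigma_implies_nu(self):
        for spikes in ([], [5.0], [12.0], [10.5, 40.0]):
            o = classify_trial(self.p_rew, spikes)
            assert o.sigma <= o.nu


class TestTrainingLoop:
    def _setup(self, seed=0, **net_kw):
        task = TaskConfig(P=6, N_p=3, N_stim=2)
        rng = np.random.default_rng(seed)
        pats = gen_task1(task, rng)
        net = NetworkConfig(model=M1Params(), **net_kw)
        return task, pats, net, rng

    def test_test_sessions_freeze_weights(self):
        task, pats, net, rng = self._setup()
        W = rng.uniform(0, 0.05, size=(1, task.P))
        before = W.copy()
        run_trial(pats[0], net, W, stdp=None, reward=None, with_noise=False)
        assert np.array_equal(W, before)

    def test_no_reward_subthreshold_weights_constant(self):
        task, pats, net, rng = self._setup()
        net = NetworkConfig(model=M1Params(eta_noise=0.0), v_noise=False)
        train = TrainConfig(n_iterations=60)
        res = run_training(
            pats, task, net, STDP_PRESETS["anti-hebbian"], RewardRule(0.0), train, rng
        )
        assert np.allclose(res.weights_sessions[0], res.weights_sessions[-1])

    def test_control_accuracy_is_non_rewarded_base_rate(self):
        task, pats, net, rng = self._setup(seed=4)
        net = NetworkConfig(model=M1Params(eta_noise=0.0), v_noise=False)
        train = TrainConfig(n_iterations=30)
        res = run_training(
            pats, task, net, STDP_PRESETS["anti-hebbian"], RewardRule(0.0), train, rng
        )
        base = sum(not p.rewarded for p in pats) / len(pats)
        assert res.accuracy[-1] == pytest.approx(base)

    def test_same_seed_identical_logs(self):
        for _ in range(2):
            task, pats, net, _ = self._setup(seed=2)
        train = TrainConfig(n_iterations=50)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            runs.append(
                run_training(pats, task, net, STDP_PRESETS["anti-hebbian"],
                             RewardRule(0.9), train, rng)
            )
        assert np.array_equal(runs[0].accuracy, runs[1].accuracy)
        assert np.array_equal(runs[0].final_weights, runs[1].final_weights)

    def test_max_accuracy_dominates_accuracy(self):
        task, pats, net, rng = self._setup(seed=6)
        train = TrainConfig(n_iterations=100)
        res = run_training(pats, task, net, STDP_PRESETS["anti-hebbian"],
                           RewardRule(0.9), train, rng)
        assert np.all(res.max_accuracy >= res.accuracy)


class TestTwoMSN:
    def test_j_zero_matches_single_msn_readout(self, rng):
        p = Pattern(((1, 10.0), (2, 10.5)), rewarded=True)
        net2 = NetworkConfig(model=M2Params(eta_noise=0.0), n_msn=2, J=0.0)
        net1 = NetworkConfig(model=M2Params(eta_noise=0.0), n_msn=1)
        W = rng.uniform(0.2, 0.8, size=(2, 2))
        o2, sp2 = run_two_msn_trial(p, net2, W.copy(), None, None)
        o1, sp1 = run_trial(p, net1, W[:1].copy(), None, None, with_noise=False)
        assert np.allclose(sp2[0], sp1[0])

    def test_silent_partner_equivalent_to_no_inhibition(self, rng):
        p = Pattern(((1, 10.0),), rewarded=True)
        net = NetworkConfig(model=M2Params(eta_noise=0.0), n_msn=2, J=-0.5)
        W = rng.uniform(0.2, 0.5, size=(2, 2))
        W[1] = 0.0  # MSN2 cannot fire
        oJ, spJ = run_two_msn_trial(p, net, W.copy(), None, None)
        net0 = NetworkConfig(model=M2Params(eta_noise=0.0), n_msn=2, J=0.0)
        o0, sp0 = run_two_msn_trial(p, net0, W.copy(), None, None)
        assert np.allclose(spJ[0], sp0[0])

    def test_positive_j_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_msn=2, J=0.1)


class TestStationaryDriver:
    def test_zero_weights_no_reward_silent(self):
        res = run_stationary_poisson(
            M1Params(), STDP_PRESETS["symmetric-ltd"], A_reward=0.0,
            rate_hz=10.0, P=5, duration_s=1.0, n_reps=3,
            rng=np.random.default_rng(0), w_init=(0.0, 0.0),
        )
        assert res.median_rate_hz == 0.0

    def test_symmetric_ltp_saturates_weights(self):
        res = run_stationary_poisson(
            M1Params(), STDP_PRESETS["symmetric-ltp"], A_reward=0.0,
            rate_hz=10.0, P=5, duration_s=5.0, n_reps=2,
            rng=np.random.default_rng(1), w_init=(0.0, 2.0),
        )
        assert np.all(res.final_weights >= 1.9)
        assert res.median_rate_hz > 10.0


class TestSinglePatternDriver:
    def test_serrated_weight_trace_in_alternation_regime(self):
        res = run_single_pattern_experiment(
            pattern_duration=20.0, w_max=0.176, n_presentations=400,
            rng=np.random.default_rng(5),
        )
        s, t1, t2 = res.stationary_freqs(200)
        assert t2 > 0 and s > 0.5
        # last channel: decays within success runs, jumps at failures
        w4 = res.weight_trace[200:, 3]
        assert np.max(np.diff(w4)) > 0.01  # sudden reward-driven increase
        assert np.min(np.diff(w4)) < 0.0  # gradual decay on successes

    def test_tiny_weight_bound_gives_pure_type2(self):
        res = run_single_pattern_experiment(
            pattern_duration=20.0, w_max=0.05, n_presentations=60,
            rng=np.random.default_rng(2),
        )
        assert res.type2_freq == 1.0
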