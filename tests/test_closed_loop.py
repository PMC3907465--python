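"""Session engine: trial loop, accuracy readouts, restarts, multi-session."""

import json

import numpy as np
import pytest

from rlbmi import (
    GeneratorConfig,
    PerturbationSpec,
    SessionConfig,
    default_session,
    run_montecarlo,
    run_multisession,
    run_session,
    sliding_accuracy,
)
from rlbmi.closed_loop import derive_seed, first_sustained_run, recovery_trials

from conftest import make_separable_session


class TestRunSession:
    def test_logs_every_trial(self, small_session):
        res = run_session(small_session, SessionConfig(seed=1))
        assert len(res.records) == 30
        assert [r.index for r in res.records] == list(range(1, 31))
        assert 0.0 <= res.overall_accuracy <= 1.0

    def test_eval_window_accuracy_matches_records(self, small_session):
        res = run_session(small_session, SessionConfig(seed=1))
        manual = np.mean([r.correct for r in res.records[5:30]])
        assert res.overall_accuracy == pytest.approx(manual)

    def test_length_mismatch_rejected(self, small_session):
        with pytest.raises(ValueError):
            run_session(small_session[:10], SessionConfig(seed=1))

    def test_separable_noiseless_session_is_perfect_after_adaptation(self):
        data = make_separable_session(n_trials=30, seed=3)
        res = run_session(data, SessionConfig(seed=4))
        assert res.overall_accuracy == 1.0

    def test_reproducible_from_config_and_seed(self, small_session):
        cfg = SessionConfig(seed=77)
        a = run_session(small_session, cfg).to_dict()
        b = run_session(small_session, cfg).to_dict()
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_snapshot_taken_at_trial_25(self, small_session):
        res = run_session(small_session, SessionConfig(seed=5))
        assert res.weights_at_trial_25 is not None
        short = run_session(
            default_session(GeneratorConfig(n_trials=10, seed=1)),
            SessionConfig(n_trials=10, eval_window=(1, 10), seed=5),
        )
        assert short.weights_at_trial_25 is None


class TestSlidingAccuracy:
    def test_all_correct_is_constant_one(self):
        assert np.array_equal(sliding_accuracy([True] * 8), np.ones(8))

    def test_alternating_oscillates_after_burn_in(self):
        vals = sliding_accuracy([True, False] * 10)
        assert set(np.round(vals[4:], 10)) == {0.4, 0.6}

    def test_first_trial_uses_truncated_window(self):
        vals = sliding_accuracy([False, True, True])
        assert vals[0] == 0.0
        assert vals[1] == 0.5
        assert vals[2] == pytest.approx(2 / 3)


class TestMonteCarlo:
    def test_single_run_reproduces_run_session(self, gen_config):
        cfg = SessionConfig(seed=9)
        mc = run_montecarlo(cfg, 1, generator=gen_config)
        from dataclasses import replace

        data = default_session(replace(gen_config, seed=derive_seed(9, 0, 0)))
        res = run_session(data, replace(cfg, seed=derive_seed(9, 0, 1)))
        assert mc.accuracies[0] == res.overall_accuracy
        assert np.array_equal(mc.results[0].sliding, res.sliding)

    def test_summary_bookkeeping(self, gen_config):
        mc = run_montecarlo(SessionConfig(seed=10), 5, generator=gen_config)
        assert mc.accuracies.shape == (5,)
        assert np.isfinite(mc.sd)
        assert mc.mean_sliding.shape == (30,)

    def test_deterministic_given_master_seed(self, gen_config):
        a = run_montecarlo(SessionConfig(seed=11), 3, generator=gen_config)
        b = run_montecarlo(SessionConfig(seed=11), 3, generator=gen_config)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_adding_runs_preserves_earlier_runs(self, gen_config):
        a = run_montecarlo(SessionConfig(seed=12), 3, generator=gen_config)
        b = run_montecarlo(SessionConfig(seed=12), 5, generator=gen_config)
        assert np.array_equal(a.accuracies, b.accuracies[:3])


class TestMultisession:
    def test_carries_trial_25_weights_bit_exact(self, gen_config):
        from rlbmi import generate_session, make_profiles

        results = run_multisession(gen_config, SessionConfig(seed=13), 2)
        carried = results[0].weights_at_trial_25
        profiles = make_profiles(gen_config)
        data2 = generate_session(
            profiles, gen_config.n_trials, gen_config.window_s, derive_seed(13, 1, 10)
        )
        cfg2 = SessionConfig(seed=derive_seed(13, 1, 11))
        redo = run_session(data2, cfg2, initial_weights=carried)
        assert np.array_equal(redo.final_weights.WH, results[1].final_weights.WH)
        assert np.array_equal(redo.final_weights.WO, results[1].final_weights.WO)

    def test_single_session_equals_run_session(self, gen_config):
        from rlbmi import generate_session, make_profiles

        results = run_multisession(gen_config, SessionConfig(seed=14), 1)
        profiles = make_profiles(gen_config)
        data = generate_session(
            profiles, gen_config.n_trials, gen_config.window_s, derive_seed(14, 0, 10)
        )
        res = run_session(data, SessionConfig(seed=derive_seed(14, 0, 11)))
        assert results[0].overall_accuracy == res.overall_accuracy

    def test_no_catastrophic_forgetting_on_stationary_input(self, gen_config):
        # later sessions start from learned weights: early-trial accuracy
        # should not collapse relative to the cold-started first session
        # (median over 20 replicates of 5 contiguous sessions each)
        firsts, laters = [], []
        for rep in range(20):
            results = run_multisession(gen_config, SessionConfig(seed=200 + rep), 5)
            accs = [np.mean([r.correct for r in res.records[:25]]) for res in results]
            firsts.append(accs[0])
            laters.append(np.mean(accs[1:]))
        assert np.median(laters) >= np.median(firsts)


class TestReadouts:
    def test_first_sustained_run_on_crafted_records(self):
        class R:
            def __init__(self, c):
                self.correct = c

        recs = [R(c) for c in [0, 1, 1, 0, 1, 1, 1, 1, 1, 0]]
        assert first_sustained_run(recs) == 5
        assert first_sustained_run([R(0)] * 6) is None

    def test_recovery_trials_counts_from_switch(self):
        class R:
            def __init__(self, c):
                self.correct = c

        # perfect before the switch at 10, dip, then recovery
        recs = [R(1)] * 10 + [R(0), R(0), R(1), R(1), R(1), R(1), R(1)]
        got = recovery_trials(recs, switch_trial=10, threshold=0.8)
        sliding = sliding_accuracy(recs)
        assert sliding[10 + got - 1] >= 0.8
        assert all(sliding[10:10 + got - 1] < 0.8)

    def test_recovery_none_when_threshold_never_met(self):
        class R:
            def __init__(self, c):
                self.correct = c

        # mixed pre-switch performance, total collapse after: the sliding
        # window never regains 0.8 once the switch passes
        recs = [R(1), R(0)] * 5 + [R(0)] * 10
        assert recovery_trials(recs, switch_trial=10) is None


def test_perturbation_mask_counts_in_log(gen_config):
    data = default_session(gen_config)
    cfg = SessionConfig(seed=15, perturbation=PerturbationSpec(kind="loss"))
    res = run_session(data, cfg)
    assert all(r.n_visible == 20 for r in res.records[:10])
    assert all(r.n_visible == 10 for r in res.records[10:])
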