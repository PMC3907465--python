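"""Critic feedback and the Hebbian reward/penalty update contract."""

import numpy as np
import pytest

from rlbmi import (
    ActorWeights,
    CriticSpec,
    LearningRates,
    NeuralState,
    ReplayBuffer,
    action_values,
    apply_update,
    epoch_update,
    forward_hidden,
    ideal_critic,
    init_weights,
    noisy_critic,
)


class TestCritics:
    @pytest.mark.parametrize(
        "action,target,f", [("A", "A", 1), ("B", "B", 1), ("A", "B", -1), ("B", "A", -1)]
    )
    def test_ideal_feedback(self, action, target, f):
        assert ideal_critic(action, target) == f

    def test_relabel_symmetry(self):
        swap = {"A": "B", "B": "A"}
        for a in "AB":
            for t in "AB":
                assert ideal_critic(a, t) == ideal_critic(swap[a], swap[t])

    def test_perfect_accuracy_matches_ideal(self, rng):
        spec = CriticSpec(accuracy=1.0)
        for a in "AB":
            for t in "AB":
                assert noisy_critic(a, t, spec, rng) == ideal_critic(a, t)

    def test_agreement_rate_binomial(self):
        rng = np.random.default_rng(1)
        spec = CriticSpec(accuracy=0.8)
        agree = [
            noisy_critic("A", "A", spec, rng) == ideal_critic("A", "A")
            for _ in range(10_000)
        ]
        se = np.sqrt(0.8 * 0.2 / 10_000)
        assert abs(np.mean(agree) - 0.8) < 3 * se

    def test_half_accuracy_is_independent_of_truth(self):
        rng = np.random.default_rng(2)
        spec = CriticSpec(accuracy=0.5)
        ideal = np.array([ideal_critic("A", t) for t in rng.choice(list("AB"), 10_000)])
        emitted = np.array(
            [noisy_critic("A", "A" if f == 1 else "B", spec, rng) for f in ideal]
        )
        phi = np.corrcoef(ideal, emitted)[0, 1]
        assert abs(phi) < 3 / np.sqrt(10_000)

    @pytest.mark.parametrize("acc", [0.4, 1.1])
    def test_accuracy_bounds_enforced(self, acc):
        with pytest.raises(ValueError):
            CriticSpec(accuracy=acc)


class TestApplyUpdate:
    def setup_method(self):
        self.w = init_weights(4, seed=0)
        self.x = np.array([0.5, -1.0, 0.25, 0.0])

    def test_reward_update_vanishes_at_saturation(self):
        # converged policy: |OutH| at numerical saturation stops adaptation
        h = np.array([1 - 1e-13, -(1 - 1e-13), 1 - 1e-13, -(1 - 1e-13), 1 - 1e-13])
        new = apply_update(self.w, self.x, h, feedback=1)
        assert np.linalg.norm(new.WH - self.w.WH) <= 1e-9
        assert np.linalg.norm(new.b - self.w.b) <= 1e-9

    def test_punishment_still_updates_at_saturation(self):
        h = np.array([1 - 1e-13, -(1 - 1e-13), 1 - 1e-13, -(1 - 1e-13), 1 - 1e-13])
        new = apply_update(self.w, self.x, h, feedback=-1)
        assert np.linalg.norm(new.WH - self.w.WH) > 1e-3

    def test_linear_in_learning_rates(self):
        h = forward_hidden(self.w, self.x)
        r1 = LearningRates(mu_H=0.01, mu_O=0.05)
        r2 = LearningRates(mu_H=0.02, mu_O=0.10)
        d1 = apply_update(self.w, self.x, h, 1, r1)
        d2 = apply_update(self.w, self.x, h, 1, r2)
        assert (d2.WH - self.w.WH) == pytest.approx(2 * (d1.WH - self.w.WH))
        assert (d2.WO - self.w.WO) == pytest.approx(2 * (d1.WO - self.w.WO))
        assert (d2.b - self.w.b) == pytest.approx(2 * (d1.b - self.w.b))

    def test_zero_input_moves_only_bias_channel(self):
        x = np.zeros(4)
        h = forward_hidden(self.w, x)
        new = apply_update(self.w, x, h, -1)
        assert np.array_equal(new.WH, self.w.WH)
        assert not np.array_equal(new.b, self.w.b)

    def test_hebbian_proportional_to_presynaptic_input(self):
        h = forward_hidden(self.w, self.x)
        new = apply_update(self.w, self.x, h, 1)
        delta = new.WH - self.w.WH
        # each row of dWH is err_i * x: columns scale with the input component
        assert np.all(delta[:, 3] == 0.0)  # x_4 = 0
        ratio = delta[:, 0] / delta[:, 2]
        assert ratio == pytest.approx(np.full(5, self.x[0] / self.x[2]))

    def test_relabel_invariance_with_swapped_output_rows(self):
        h = forward_hidden(self.w, self.x)
        swapped = ActorWeights(self.w.WH.copy(), self.w.b.copy(), self.w.WO[::-1].copy())
        new = apply_update(self.w, self.x, h, -1)
        new_swapped = apply_update(swapped, self.x, h, -1)
        assert new_swapped.WO == pytest.approx(new.WO[::-1])
        assert new_swapped.WH == pytest.approx(new.WH)

    def test_invalid_feedback_rejected(self):
        with pytest.raises(ValueError):
            apply_update(self.w, self.x, forward_hidden(self.w, self.x), 0)


class TestEpochUpdate:
    def test_single_trial_buffer_runs_ten_passes(self, rng):
        w = init_weights(3, seed=1)
        state = NeuralState(x=np.array([0.5, -0.5, 1.0]))
        buffer = ReplayBuffer(passes=10)
        buffer.append(state, "A")
        got = epoch_update(w, buffer, rng=np.random.default_rng(0))
        # oracle: ten explicit forward/update applications
        expect = w
        oracle_rng = np.random.default_rng(0)
        from rlbmi.actor import select_action

        for _ in range(10):
            h = forward_hidden(expect, state.x)
            decision = select_action(action_values(expect, h), oracle_rng, h)
            f = ideal_critic(decision.action, "A")
            expect = apply_update(expect, state.x, h, f)
        assert got.WH == pytest.approx(expect.WH)
        assert got.WO == pytest.approx(expect.WO)

    def test_zero_passes_is_identity(self, rng):
        w = init_weights(3, seed=2)
        buffer = ReplayBuffer(passes=10)
        buffer.append(NeuralState(x=np.zeros(3)), "B")
        out = epoch_update(w, buffer, rng=rng, passes=0)
        assert np.array_equal(out.WH, w.WH)

    def test_empty_buffer_is_noop(self, rng):
        w = init_weights(3, seed=3)
        assert epoch_update(w, ReplayBuffer(), rng=rng) is w

    def test_separable_two_trial_buffer_reaches_fixed_point(self):
        w = init_weights(2, seed=4)
        buffer = ReplayBuffer(passes=10)
        buffer.append(NeuralState(x=np.array([1.0, -1.0])), "A")
        buffer.append(NeuralState(x=np.array([-1.0, 1.0])), "B")
        rng = np.random.default_rng(5)
        for _ in range(30):
            w = epoch_update(w, buffer, rng=rng)
        for state, target in buffer.entries:
            h = forward_hidden(w, state.x)
            av = action_values(w, h)
            assert ("A", "B")[int(np.argmax(av))] == target
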