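"""Critic feedback and the Hebbian reward/penalty weight update.

The critic reduces each trial to one bit: f = +1 if the selected action
was rewarded (matched the illuminated target) and f = -1 otherwise.
That global bit gates a local, layer-wise Hebbian update: writing
``post`` for a node's tanh activation, ``pre`` for its input vector and
``S()`` for the sign function, each weight block changes by

    dW = mu * [ f * (S(post) - post)  +  (f - 1) * post ] * pre
       = mu * (f * S(post) - post) * pre

Under reward (f = +1) only the first term is active: it pushes the node
toward the sign of its current output and *vanishes* as |post| -> 1, so
adaptation stops automatically once the policy has committed.  Under
punishment (f = -1) both terms act, driving the node toward the
opposite sign at full strength even from saturation.  The hidden layer
uses ``pre = [X; 1]`` (the bias learns as a weight on a constant +1
input) with rate mu_H = 0.01; the output layer uses ``pre = S(OutH)``
and ``post = tanh(AV_j)`` with rate mu_O = 0.05.  Both output nodes are
updated with the same global feedback.

To speed early adaptation the session keeps a replay buffer of every
completed trial; after each robot action the whole buffer is swept ten
times ("epoching"), re-evaluating each stored trial with the current
weights and re-deriving feedback from the stored target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .actor import ActorWeights, action_values, forward_hidden, select_action, sign
from .preprocess import NeuralState

__all__ = [
    "CriticSpec",
    "LearningRates",
    "ReplayBuffer",
    "Critic",
    "ideal_critic",
    "noisy_critic",
    "make_critic",
    "apply_update",
    "epoch_update",
]

# critic signature: (action, target, rng) -> +1 | -1
Critic = Callable[[str, str, np.random.Generator], int]


@dataclass(frozen=True)
class CriticSpec:
    """Probability that emitted feedback agrees with the ideal critic."""

    accuracy: float = 1.0

    def __post_init__(self) -> None:
        if not 0.5 <= self.accuracy <= 1.0:
            raise ValueError("critic accuracy must lie in [0.5, 1.0]")


@dataclass(frozen=True)
class LearningRates:
    mu_H: float = 0.01
    mu_O: float = 0.05

    def __post_init__(self) -> None:
        if self.mu_H <= 0 or self.mu_O <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class ReplayBuffer:
    """Chronological (neural state, target) pairs for the current session."""

    passes: int = 10
    entries: list[tuple[NeuralState, str]] = field(default_factory=list)

    def append(self, state: NeuralState, target: str) -> None:
        self.entries.append((state, target))

    def __len__(self) -> int:
        return len(self.entries)


def ideal_critic(action: str, target: str, rng: np.random.Generator | None = None) -> int:
    """Always-accurate feedback: +1 iff the action hit the target."""
    if action not in ("A", "B") or target not in ("A", "B"):
        raise ValueError("action and target must be 'A' or 'B'")
    return 1 if action == target else -1


def noisy_critic(
    action: str, target: str, spec: CriticSpec, rng: np.random.Generator
) -> int:
    """Feedback agreeing with the ideal critic with probability spec.accuracy."""
    f = ideal_critic(action, target)
    return f if rng.random() < spec.accuracy else -f


def make_critic(spec: CriticSpec | None = None) -> Critic:
    """Bind a CriticSpec into the common critic signature."""
    if spec is None or spec.accuracy >= 1.0:
        return ideal_critic
    return lambda action, target, rng: noisy_critic(action, target, spec, rng)


def apply_update(
    weights: ActorWeights,
    x: np.ndarray,
    hidden_out: np.ndarray,
    feedback: int,
    rates: LearningRates = LearningRates(),
) -> ActorWeights:
    """One reward/penalty update of both layers; returns new weights."""
    if feedback not in (1, -1):
        raise ValueError("feedback must be +1 or -1")
    x = np.asarray(x, dtype=float)
    hidden_out = np.asarray(hidden_out, dtype=float)
    if x.shape[0] != weights.n_inputs or hidden_out.shape[0] != weights.WO.shape[1]:
        raise ValueError("shape mismatch between weights and activations")
    f = float(feedback)

    # hidden layer: pre = [x; 1], post = OutH
    err_h = f * sign(hidden_out) - hidden_out
    new_WH = weights.WH + rates.mu_H * np.outer(err_h, x)
    new_b = weights.b + rates.mu_H * err_h

    # output layer: pre = S(OutH), post = tanh(AV)
    s_h = sign(hidden_out)
    av = weights.WO @ s_h
    out_o = np.tanh(av)
    err_o = f * sign(av) - out_o
    new_WO = weights.WO + rates.mu_O * np.outer(err_o, s_h)

    return ActorWeights(WH=new_WH, b=new_b, WO=new_WO)


def epoch_update(
    weights: ActorWeights,
    buffer: ReplayBuffer,
    critic: Critic = ideal_critic,
    rates: LearningRates = LearningRates(),
    rng: np.random.Generator | None = None,
    passes: int | None = None,
) -> ActorWeights:
    """Sweep the replay buffer ``passes`` times (default: buffer.passes).

    Each sweep walks the buffered trials in order, re-runs the forward
    pass with the current weights, takes the greedy action, asks the
    critic for feedback against the stored target, and applies the
    reward/penalty update.  An empty buffer is a documented no-op.
    """
    if passes is None:
        passes = buffer.passes
    if passes < 0:
        raise ValueError("passes must be >= 0")
    if len(buffer) == 0:
        return weights
    if rng is None:
        rng = np.random.default_rng()
    w = weights
    for _ in range(passes):
        for state, target in buffer.entries:
            hidden = forward_hidden(w, state.x)
            decision = select_action(action_values(w, hidden), rng, hidden)
            f = critic(decision.action, target, rng)
            w = apply_update(w, state.x, hidden, f, rates)
    return w
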