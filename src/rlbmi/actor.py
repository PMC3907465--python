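"""The actor: a parsimonious 3-layer feedforward network.

Five hidden nodes squash the normalized neural input through tanh,
    OutH_i = tanh(WH_i . X + b_i),
and two output nodes read the *signs* of the hidden outputs to form
action values,
    AV_j = WO_j . S(OutH),
where S() maps positive values to +1 and negative values to -1.  The
robot action with the highest action value is taken each trial; exact
ties are broken by a fair coin from the session RNG.

Weights are initialized i.i.d. uniform on [-0.075, +0.075], so the very
first actions are effectively random exploration.  The bias is carried
as a weight on a constant +1 input and therefore learns like any other
hidden-layer weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ACTIONS",
    "N_HIDDEN",
    "INIT_SCALE",
    "ActorWeights",
    "ActionDecision",
    "init_weights",
    "forward_hidden",
    "sign",
    "action_values",
    "select_action",
]

ACTIONS = ("A", "B")
N_HIDDEN = 5
N_ACTIONS = 2
INIT_SCALE = 0.075


@dataclass
class ActorWeights:
    """WH: (hidden, n) input weights; b: (hidden,) bias; WO: (actions, hidden)."""

    WH: np.ndarray
    b: np.ndarray
    WO: np.ndarray

    def __post_init__(self) -> None:
        self.WH = np.asarray(self.WH, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.WO = np.asarray(self.WO, dtype=float)
        h, n = self.WH.shape
        if self.b.shape != (h,) or self.WO.shape[1] != h:
            raise ValueError("inconsistent weight shapes")
        if not (
            np.all(np.isfinite(self.WH))
            and np.all(np.isfinite(self.b))
            and np.all(np.isfinite(self.WO))
        ):
            raise ValueError("weights must be finite")

    @property
    def n_inputs(self) -> int:
        return self.WH.shape[1]

    def copy(self) -> "ActorWeights":
        return ActorWeights(self.WH.copy(), self.b.copy(), self.WO.copy())

    def to_dict(self) -> dict:
        return {
            "WH": self.WH.tolist(),
            "b": self.b.tolist(),
            "WO": self.WO.tolist(),
            "shapes": {"WH": list(self.WH.shape), "b": list(self.b.shape), "WO": list(self.WO.shape)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ActorWeights":
        return cls(np.array(d["WH"]), np.array(d["b"]), np.array(d["WO"]))


@dataclass(frozen=True)
class ActionDecision:
    action: str
    action_values: np.ndarray
    hidden_out: np.ndarray
    tie_broken: bool = False


def init_weights(
    n: int,
    seed: int | np.random.Generator,
    n_hidden: int = N_HIDDEN,
    n_actions: int = N_ACTIONS,
    scale: float = INIT_SCALE,
) -> ActorWeights:
    """Small random initial weights, uniform on [-scale, +scale]."""
    if n < 1:
        raise ValueError("need at least one input signal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return ActorWeights(
        WH=rng.uniform(-scale, scale, size=(n_hidden, n)),
        b=rng.uniform(-scale, scale, size=n_hidden),
        WO=rng.uniform(-scale, scale, size=(n_actions, n_hidden)),
    )


def forward_hidden(weights: ActorWeights, x: np.ndarray) -> np.ndarray:
    """Hidden-layer outputs OutH = tanh(WH.x + b), each in (-1, 1)."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != weights.n_inputs:
        raise ValueError(
            f"input length {x.shape[0]} != actor n_inputs {weights.n_inputs}"
        )
    return np.tanh(weights.WH @ x + weights.b)


def sign(v: np.ndarray) -> np.ndarray:
    """Binarize: positive -> +1, negative -> -1, with sign(0) := +1."""
    v = np.asarray(v, dtype=float)
    return np.where(v >= 0.0, 1.0, -1.0)


def action_values(weights: ActorWeights, hidden_out: np.ndarray) -> np.ndarray:
    """AV_j = WO_j . S(OutH); no output bias."""
    hidden_out = np.asarray(hidden_out, dtype=float)
    if hidden_out.shape[0] != weights.WO.shape[1]:
        raise ValueError("hidden_out length does not match WO")
    return weights.WO @ sign(hidden_out)


def select_action(
    av: np.ndarray,
    rng: np.random.Generator,
    hidden_out: np.ndarray | None = None,
) -> ActionDecision:
    """Greedy action; exact ties resolved by a fair coin (and flagged)."""
    av = np.asarray(av, dtype=float)
    if not np.all(np.isfinite(av)):
        raise ValueError("action values must be finite")
    if av[0] == av[1]:
        idx = int(rng.integers(2))
        tie = True
    else:
        idx = int(np.argmax(av))
        tie = False
    return ActionDecision(
        action=ACTIONS[idx],
        action_values=av,
        hidden_out=np.empty(0) if hidden_out is None else hidden_out,
        tie_broken=tie,
    )
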