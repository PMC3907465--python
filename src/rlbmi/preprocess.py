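"""Real-time normalization of spike counts to the [-1, 1] actor input.

The decoder never sees raw counts: each signal is rescaled against a
running estimate of its maximum count, updated trial by trial, mapping a
count ``c`` to ``2 * c / max_estimate - 1`` (so the running maximum maps
to +1 and silence to -1).  Masked channels -- signals the recording
system is not currently detecting -- contribute exactly 0 drive and
leave the running estimate untouched: an undetected unit is absence of
evidence, not a silent unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NormalizerState", "NeuralState", "update_and_normalize"]


@dataclass(frozen=True)
class NormalizerState:
    """Per-signal running maximum count, floored to avoid division by zero."""

    max_estimate: np.ndarray
    floor: float = 1.0

    @classmethod
    def fresh(cls, n_signals: int, floor: float = 1.0) -> "NormalizerState":
        if n_signals < 1:
            raise ValueError("n_signals must be >= 1")
        if floor <= 0:
            raise ValueError("floor must be positive")
        return cls(max_estimate=np.full(n_signals, floor, dtype=float), floor=floor)


@dataclass(frozen=True)
class NeuralState:
    """Normalized actor input X, every component in [-1, 1] (masked -> 0)."""

    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if np.any(np.abs(x) > 1.0):
            raise ValueError("neural state components must lie in [-1, 1]")
        object.__setattr__(self, "x", x)


def update_and_normalize(
    counts: np.ndarray,
    state: NormalizerState,
    mask: np.ndarray | None = None,
) -> tuple[NeuralState, NormalizerState]:
    """Fold one trial's counts into the running maxima and normalize.

    Parameters
    ----------
    counts
        Nonnegative spike counts, one per signal.
    state
        Running normalizer state; returned updated (input untouched).
    mask
        Boolean visibility per channel (True = detected).  Hidden
        channels output exactly 0 and do not update the running maximum.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    n = counts.shape[0]
    if state.max_estimate.shape[0] != n:
        raise ValueError("counts and normalizer state disagree on n_signals")
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != n:
        raise ValueError("mask length must equal n_signals")

    new_max = np.where(mask, np.maximum(state.max_estimate, counts), state.max_estimate)
    x = np.zeros(n, dtype=float)
    visible = mask
    x[visible] = np.clip(2.0 * counts[visible] / new_max[visible] - 1.0, -1.0, 1.0)
    return NeuralState(x=x), NormalizerState(max_estimate=new_max, floor=state.floor)
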