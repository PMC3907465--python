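"""Declarative input-space perturbations.

Emulates neural signals appearing or disappearing from the recording
system: ``loss`` abruptly hides a random fraction of channels after a
switch trial; ``gain`` starts with that fraction hidden and reveals
them ("found" neurons).  Hidden channels stay in the input vector at
fixed dimensionality -- the actor never resizes -- and present exactly
zero drive through the normalizer's masking contract.

Masks are pure functions of (spec, trial_index, n_signals): the affected
channel subset is fixed by ``channel_seed``, so loss and gain specs with
the same seed perturb identical channels (paired experiments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PerturbationSpec", "mask_for_trial", "graded_loss_masks"]


@dataclass(frozen=True)
class PerturbationSpec:
    """Which channels are hidden on which trials.

    kind='loss': all visible through ``switch_trial``, the selected
    fraction hidden afterwards.  kind='gain': the selected fraction
    hidden through ``switch_trial``, all visible afterwards.
    kind='none': identity mask always.
    """

    kind: str = "none"
    fraction: float = 0.5
    switch_trial: int = 10
    channel_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("loss", "gain", "none"):
            raise ValueError("kind must be 'loss', 'gain' or 'none'")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.switch_trial < 0:
            raise ValueError("switch_trial must be >= 0")


def _affected_channels(spec: PerturbationSpec, n_signals: int) -> np.ndarray:
    n_hide = int(round(spec.fraction * n_signals))
    rng = np.random.default_rng(spec.channel_seed)
    return rng.permutation(n_signals)[:n_hide]


def mask_for_trial(spec: PerturbationSpec, trial_index: int, n_signals: int) -> np.ndarray:
    """Boolean visibility vector (True = channel detected) for one trial."""
    mask = np.ones(n_signals, dtype=bool)
    if spec.kind == "none" or spec.fraction == 0.0:
        return mask
    affected = _affected_channels(spec, n_signals)
    if spec.kind == "loss":
        if trial_index > spec.switch_trial:
            mask[affected] = False
    else:  # gain
        if trial_index <= spec.switch_trial:
            mask[affected] = False
    return mask


def graded_loss_masks(
    fractions, n_signals: int, n_draws: int, seed: int
) -> dict[float, np.ndarray]:
    """Random channel-loss masks for each fraction.

    Returns, per fraction, an (n_draws, n_signals) boolean array where
    False marks a lost channel; each draw hides an independent random
    subset of exactly ``round(fraction * n_signals)`` channels.
    """
    rng = np.random.default_rng(seed)
    out: dict[float, np.ndarray] = {}
    for frac in fractions:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        n_hide = int(round(frac * n_signals))
        masks = np.ones((n_draws, n_signals), dtype=bool)
        for d in range(n_draws):
            masks[d, rng.permutation(n_signals)[:n_hide]] = False
        out[float(frac)] = masks
    return out
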