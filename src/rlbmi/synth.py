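"""Synthetic two-class spike-count sessions.

Emulates the structure of motor-cortex recordings from a two-target
reaching task: on each trial a population of multiunit/single-unit
signals is counted in a fixed window after the go cue.  ``A`` trials
carry modulated firing on a subset of signals; ``B`` trials show static
(baseline) firing on every signal.  Spike counts are Poisson given the
trial class, the minimal model for windowed counts.

Trial classes are presented in a pseudo-random, near-balanced order:
each consecutive block of 10 trials holds 5 A and 5 B trials in random
order (a final partial block is balanced to within one trial).

All randomness flows from a single session seed through named
substreams, so labels and counts are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalProfile",
    "GeneratorConfig",
    "TrialRecord",
    "make_profiles",
    "generate_session",
    "scramble_session",
    "session_to_frame",
    "frame_to_session",
    "write_session_csv",
    "read_session_csv",
]

LABELS = ("A", "B")


@dataclass(frozen=True)
class SignalProfile:
    """Firing-rate profile of one recorded signal.

    ``baseline_rate`` applies on B (static) trials; ``a_rate`` on A
    (modulated) trials.  Unmodulated signals fire at baseline on both.
    """

    baseline_rate: float
    a_rate: float
    modulated: bool

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.a_rate < 0:
            raise ValueError("firing rates must be nonnegative")
        if not self.modulated and self.a_rate != self.baseline_rate:
            raise ValueError("unmodulated signal must have a_rate == baseline_rate")

    def rate(self, label: str) -> float:
        return self.a_rate if label == "A" else self.baseline_rate


@dataclass(frozen=True)
class GeneratorConfig:
    """Session-generator settings.

    Defaults give ~20 signals (the recorded arrays yielded ~18-21 usable
    signals) counted over a 2 s post-go window, with 60% of signals
    doubling their rate on A trials -- strongly separable classes in
    line with the ~90% closed-loop performance regime being emulated.
    """

    n_signals: int = 20
    frac_modulated: float = 0.6
    window_s: float = 2.0
    baseline_rate: float = 8.0
    a_rate: float = 16.0
    n_trials: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signals < 1:
            raise ValueError("n_signals must be >= 1")
        if not 0.0 <= self.frac_modulated <= 1.0:
            raise ValueError("frac_modulated must lie in [0, 1]")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    """One trial: integer spike counts per signal, class label, 1-based index."""

    counts: np.ndarray
    label: str
    index: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be a vector")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named substream of a session seed (labels and counts independent)."""
    key = int.from_bytes(name.encode(), "little") % (2**32)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def make_profiles(config: GeneratorConfig) -> list[SignalProfile]:
    """Assign modulated/unmodulated profiles to the configured signals.

    Exactly ``round(n_signals * frac_modulated)`` signals are modulated;
    which ones is a seeded permutation so the assignment is deterministic
    per config.
    """
    n_mod = int(round(config.n_signals * config.frac_modulated))
    rng = _substream(config.seed, "profiles")
    modulated_idx = set(rng.permutation(config.n_signals)[:n_mod].tolist())
    profiles = []
    for i in range(config.n_signals):
        if i in modulated_idx:
            profiles.append(
                SignalProfile(config.baseline_rate, config.a_rate, modulated=True)
            )
        else:
            profiles.append(
                SignalProfile(config.baseline_rate, config.baseline_rate, modulated=False)
            )
    return profiles


def _balanced_labels(n_trials: int, rng: np.random.Generator) -> list[str]:
    """Pseudo-random label order, balanced 5/5 within each block of 10."""
    labels: list[str] = []
    remaining = n_trials
    while remaining > 0:
        block_n = min(10, remaining)
        n_a = block_n // 2
        n_b = block_n - n_a
        # odd partial block: coin flip decides which class gets the extra trial
        if block_n % 2 == 1 and rng.random() < 0.5:
            n_a, n_b = n_b, n_a
        block = ["A"] * n_a + ["B"] * n_b
        rng.shuffle(block)
        labels.extend(block)
        remaining -= block_n
    return labels


def generate_session(
    profiles: Sequence[SignalProfile],
    n_trials: int,
    window_s: float,
    seed: int,
) -> list[TrialRecord]:
    """Draw one session of Poisson spike-count trials.

    Counts for signal ``i`` on a trial with label ``y`` are
    Poisson(rate_i(y) * window_s), independent across signals and trials.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    label_rng = _substream(seed, "labels")
    count_rng = _substream(seed, "counts")
    labels = _balanced_labels(n_trials, label_rng)
    session = []
    for t, label in enumerate(labels, start=1):
        means = np.array([p.rate(label) * window_s for p in profiles])
        counts = count_rng.poisson(means)
        session.append(TrialRecord(counts=counts, label=label, index=t))
    return session


def default_session(config: GeneratorConfig) -> list[TrialRecord]:
    """Profiles + session draw in one call, all from ``config``."""
    profiles = make_profiles(config)
    return generate_session(profiles, config.n_trials, config.window_s, config.seed)


def scramble_session(session: Sequence[TrialRecord], seed: int) -> list[TrialRecord]:
    """Surrogate control: decouple neural data from trial labels.

    The label sequence is kept while whole-trial count vectors are
    permuted uniformly at random, destroying any consistent association
    between population activity and the target -- the multiset of count
    vectors is untouched.
    """
    if len(session) < 1:
        raise ValueError("session must be non-empty")
    rng = _substream(seed, "scramble")
    perm = rng.permutation(len(session))
    return [
        replace(session[t], counts=session[perm[t]].counts, index=t + 1)
        for t in range(len(session))
    ]


# ---------------------------------------------------------------------------
# Session CSV round-trip: columns trial, label, sig_001...sig_NNN

def session_to_frame(session: Sequence[TrialRecord]) -> pd.DataFrame:
    n = len(session[0].counts)
    cols = [f"sig_{i + 1:03d}" for i in range(n)]
    frame = pd.DataFrame(
        np.stack([t.counts for t in session]), columns=cols, dtype=np.int64
    )
    frame.insert(0, "label", [t.label for t in session])
    frame.insert(0, "trial", [t.index for t in session])
    return frame


def frame_to_session(frame: pd.DataFrame) -> list[TrialRecord]:
    sig_cols = [c for c in frame.columns if c.startswith("sig_")]
    return [
        TrialRecord(
            counts=row[sig_cols].to_numpy(dtype=np.int64),
            label=str(row["label"]),
            index=int(row["trial"]),
        )
        for _, row in frame.iterrows()
    ]


def write_session_csv(session: Sequence[TrialRecord], path) -> None:
    session_to_frame(session).to_csv(path, index=False)


def read_session_csv(path) -> list[TrialRecord]:
    return frame_to_session(pd.read_csv(path))
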