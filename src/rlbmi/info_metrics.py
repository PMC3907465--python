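"""Entropy and per-signal mutual information with the target label.

Quantifies how much each signal's windowed spike count says about the
binary target: I(X;Y) = H(Y) - H(Y|X) in bits, with H(Y) = 1 bit when A
and B trials are equally likely.  Counts are discretized as raw integer
categories when few distinct values occur, else by quantile binning
(the plug-in, maximum-likelihood estimator; no bias correction).

The input-loss analysis averages per-signal MI over *all* nominal
channels with lost channels contributing zero bits (a zeroed signal is
constant, hence uninformative), relative to the intact average -- so
losing a random half of the signals removes, in expectation, half of
the available information.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .synth import TrialRecord

__all__ = [
    "entropy",
    "mutual_information",
    "session_mi",
    "avg_mi_under_loss",
]

MAX_RAW_CATEGORIES = 16
DEFAULT_QUANTILE_BINS = 8


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits, with 0*log(0) := 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("need a probability vector summing to 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _discretize(values: np.ndarray, n_bins: int | None) -> np.ndarray:
    """Integer category codes: raw values when few, else quantile bins."""
    values = np.asarray(values)
    uniq = np.unique(values)
    if n_bins is None and uniq.size <= MAX_RAW_CATEGORIES:
        return np.searchsorted(uniq, values)
    bins = n_bins or DEFAULT_QUANTILE_BINS
    qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, values, side="right")


def mutual_information(values, labels, n_bins: int | None = None) -> float:
    """Plug-in MI (bits) between one signal's counts and the trial label."""
    values = np.asarray(values)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels must align")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    codes = _discretize(values, n_bins)
    joint = pd.crosstab(codes, labels).to_numpy(dtype=float)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    h_y = entropy(py)
    h_y_given_x = 0.0
    for i in range(joint.shape[0]):
        if px[i] > 0:
            h_y_given_x += px[i] * entropy(joint[i] / px[i])
    mi = h_y - h_y_given_x
    return float(np.clip(mi, 0.0, h_y))


def session_mi(session: Sequence[TrialRecord], n_bins: int | None = None) -> np.ndarray:
    """Per-signal MI with the label across a session."""
    counts = np.stack([t.counts for t in session])
    labels = np.array([t.label for t in session])
    return np.array(
        [mutual_information(counts[:, i], labels, n_bins) for i in range(counts.shape[1])]
    )


def avg_mi_under_loss(
    session: Sequence[TrialRecord],
    fractions,
    n_draws: int = 500,
    seed: int = 0,
    n_bins: int | None = None,
) -> pd.DataFrame:
    """Relative average MI retained under random channel loss.

    For each loss fraction, draws ``n_draws`` random channel subsets to
    zero; lost signals contribute 0 bits and the average runs over all
    nominal channels.  Returns a frame with columns ``fraction``,
    ``relative_mi`` (mean over draws, as a fraction of the intact
    average) and ``sd``.
    """
    mi = session_mi(session, n_bins)
    n = mi.shape[0]
    intact = mi.mean()
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        n_lost = int(round(frac * n))
        rel = np.empty(n_draws)
        for d in range(n_draws):
            lost = rng.permutation(n)[:n_lost]
            kept = mi.copy()
            kept[lost] = 0.0
            rel[d] = kept.mean() / intact if intact > 0 else 0.0
        rows.append(
            {"fraction": float(frac), "relative_mi": float(rel.mean()), "sd": float(rel.std(ddof=1)) if n_draws > 1 else 0.0}
        )
    return pd.DataFrame(rows)
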