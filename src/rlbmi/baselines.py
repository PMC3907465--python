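"""Static Wiener classifier baseline.

The non-adaptive comparison decoder: a least-squares linear map from the
normalized neural input (plus intercept) to one-hot class targets,
fitted once on the first five trials of a session and frozen.  With 5
training trials and n+1 >= 21 unknowns per class the system is
underdetermined; the minimum-norm pseudoinverse solution is used
(parameter-free and deterministic), with an optional ridge penalty.

Because the weights never change after fitting, any later shift of the
input space -- channels lost, or new channels appearing -- degrades this
baseline permanently, which is exactly the contrast the adaptive decoder
is measured against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["WienerModel", "fit_wiener", "predict_wiener", "wiener_session_accuracy"]

ACTIONS = ("A", "B")


@dataclass
class WienerModel:
    """(2, n+1) weight matrix, last column the intercept (if fitted with one)."""

    W: np.ndarray
    intercept: bool
    n_train: int

    @property
    def fitted(self) -> bool:
        return self.W.size > 0


def _design(X: np.ndarray, intercept: bool) -> np.ndarray:
    if intercept:
        return np.hstack([X, np.ones((X.shape[0], 1))])
    return X


def fit_wiener(
    X: np.ndarray,
    labels,
    intercept: bool = True,
    ridge: float = 0.0,
) -> WienerModel:
    """Least-squares fit of one-hot class scores on normalized inputs.

    ``X`` is (m, n) with one row per training trial (the protocol uses
    the first five trials of a session).  A single-class training set is
    accepted with a warning -- the model then scores only that class.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if X.shape[0] != len(labels):
        raise ValueError("X rows and labels must align")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training trials")
    if len(set(labels)) < 2:
        warnings.warn("Wiener training set contains a single class", stacklevel=2)
    Y = np.column_stack([[1.0 if l == a else 0.0 for l in labels] for a in ACTIONS])
    D = _design(X, intercept)
    if ridge > 0.0:
        G = D.T @ D + ridge * np.eye(D.shape[1])
        W = (np.linalg.solve(G, D.T @ Y)).T
    else:
        W = (np.linalg.pinv(D) @ Y).T  # minimum-norm solution
    return WienerModel(W=W, intercept=intercept, n_train=X.shape[0])


def predict_wiener(model: WienerModel, x: np.ndarray) -> str:
    """Argmax of the two linear scores; exact ties go to class A."""
    if not model.fitted:
        raise RuntimeError("Wiener model is not fitted")
    x = np.asarray(x, dtype=float)
    d = np.append(x, 1.0) if model.intercept else x
    scores = model.W @ d
    return ACTIONS[0] if scores[0] >= scores[1] else ACTIONS[1]


def wiener_session_accuracy(
    model: WienerModel,
    X: np.ndarray,
    labels,
    eval_slice: slice | None = None,
) -> float:
    """Accuracy of the frozen model over (a slice of) a normalized session."""
    labels = list(labels)
    preds = [predict_wiener(model, x) for x in np.asarray(X, dtype=float)]
    if eval_slice is not None:
        preds = preds[eval_slice]
        labels = labels[eval_slice]
    return float(np.mean([p == l for p, l in zip(preds, labels)]))
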