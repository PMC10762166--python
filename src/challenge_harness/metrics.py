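"""Assessment statistics: Matthews correlation, F1, and mean squared error.

Mortality predictions are scored as a binary classification with
"Mortality" as the positive class (configurable); FSS predictions are
scored by MSE over the subjects whose observed FSS is known.  The scorers
are authored here so their zero-denominator conventions are explicit;
tests cross-check them against an independent implementation.

Conventions for degenerate confusion matrices:

* MCC: if any of the four marginal sums (TP+FP, TP+FN, TN+FP, TN+FN) is
  zero the coefficient is undefined; it is reported as 0.0, the dominant
  convention (no better than chance).
* F1: if 2*TP + FP + FN == 0 (no positives observed or predicted) F1 is
  reported as 0.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "ConfusionCounts", "confusion_counts", "mcc", "f1", "mse",
    "POSITIVE_CLASS", "MORTALITY_LABELS",
]

POSITIVE_CLASS = "Mortality"
MORTALITY_LABELS = ("Mortality", "Alive")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion-matrix cells; positive class is "Mortality"."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ParameterError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(observed: Sequence[str], predicted: Sequence[str],
                     positive: str = POSITIVE_CLASS) -> ConfusionCounts:
    """Tabulate confusion counts from observed and predicted labels."""
    if len(observed) != len(predicted):
        raise ParameterError(
            f"length mismatch: {len(observed)} observed vs {len(predicted)} predicted")
    obs = np.asarray(observed) == positive
    pred = np.asarray(predicted) == positive
    return ConfusionCounts(
        tp=int(np.sum(obs & pred)),
        tn=int(np.sum(~obs & ~pred)),
        fp=int(np.sum(~obs & pred)),
        fn=int(np.sum(obs & ~pred)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient, in [-1, 1].

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0.0 when any
    marginal sum vanishes.
    """
    if c.total == 0:
        raise ParameterError("confusion counts are all zero")
    denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom2 == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom2)


def f1(c: ConfusionCounts) -> float:
    """F1 score for the positive class, in [0, 1]: 2TP / (2TP + FP + FN)."""
    if c.total == 0:
        raise ParameterError("confusion counts are all zero")
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 0.0
    return 2 * c.tp / denom


def mse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean squared error between observed and predicted FSS values.

    Both vectors must cover exactly the known-FSS subjects, in the same
    subject order (validation enforces completeness upstream).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ParameterError(
            f"length mismatch: {obs.shape[0]} observed vs {pred.shape[0]} predicted")
    if obs.size == 0:
        raise ParameterError("cannot score an empty FSS vector")
    return float(np.mean((obs - pred) ** 2))
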