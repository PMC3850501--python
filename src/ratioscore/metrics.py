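"""Confusion-matrix evaluation for binary case/control calls."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts and the derived sensitivity/specificity.

    A rate whose denominator is zero is reported as None (undefined),
    never silently as 0.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None

    @property
    def accuracy(self) -> float | None:
        n = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / n if n else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def compute_metrics(calls, truth) -> EvalMetrics:
    """Tabulate a confusion matrix from binary call and truth vectors."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError(f"length mismatch: {calls.shape} vs {truth.shape}")
    return EvalMetrics(
        tp=int((calls & truth).sum()),
        fn=int((~calls & truth).sum()),
        tn=int((~calls & ~truth).sum()),
        fp=int((calls & ~truth).sum()),
    )


def percent(rate: float | None) -> int | None:
    """Render a rate as a whole-number percentage (None stays None)."""
    return None if rate is None else int(round(100 * rate))
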