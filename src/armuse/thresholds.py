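"""Fixed count thresholds and the bilateral combination rule.

The conventional rule classifies an epoch as functional when its vector-
magnitude activity count exceeds 2 (unilateral use) or 0 (the per-side
component of bilateral use).  Bilateral functional activity is the
conjunction of the two unilateral classifications, both for predictions and
for the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThresholdModel",
    "classify_threshold",
    "conventional_models",
    "bilateral_combine",
    "bilateral_ground_truth",
]

GREATER = ">"
GREATER_EQUAL = ">="


@dataclass(frozen=True)
class ThresholdModel:
    """A side-specific count cutoff with an explicit comparison convention."""

    side: str
    cutoff: float
    comparison: str = GREATER_EQUAL

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be non-negative")
        if self.comparison not in (GREATER, GREATER_EQUAL):
            raise ValueError("comparison must be '>' or '>='")

    def to_dict(self) -> dict:
        return {"side": self.side, "cutoff": self.cutoff,
                "comparison": self.comparison}

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdModel":
        return cls(side=d["side"], cutoff=d["cutoff"],
                   comparison=d["comparison"])


def classify_threshold(counts: np.ndarray, model: ThresholdModel) -> np.ndarray:
    """Per-epoch functional/non-functional decision under a threshold model."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("activity counts must be non-negative")
    if model.comparison == GREATER:
        return counts > model.cutoff
    return counts >= model.cutoff


def conventional_models(side: str = "any") -> tuple[ThresholdModel, ThresholdModel]:
    """The validated conventional cutoffs: >2 unilateral, >0 bilateral component."""
    return (ThresholdModel(side=side, cutoff=2.0, comparison=GREATER),
            ThresholdModel(side=side, cutoff=0.0, comparison=GREATER))


def bilateral_combine(pred_affected: np.ndarray,
                      pred_unaffected: np.ndarray) -> np.ndarray:
    """Bilateral functional activity: both arms classified functional."""
    return np.logical_and(pred_affected, pred_unaffected)


def bilateral_ground_truth(label_affected: np.ndarray,
                           label_unaffected: np.ndarray) -> np.ndarray:
    """1 iff both sides' ground-truth labels are functional; inputs aligned."""
    a = np.asarray(label_affected)
    u = np.asarray(label_unaffected)
    if a.shape != u.shape:
        raise ValueError("side label sequences are misaligned")
    return ((a == 1) & (u == 1)).astype(int)
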