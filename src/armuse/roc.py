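"""ROC-optimal count thresholds (Youden cutpoint) with DeLong AUC intervals.

``OptimalThresholdModel`` is fitted from per-epoch counts and binary labels;
its results carry the Mann-Whitney AUC with a DeLong 95% confidence
interval, the cutoff maximizing sensitivity + specificity over the observed
count values (classification convention ">="), and the operating point at
that cutoff.  Per-subject fits support the exploratory individual-threshold
analysis and its correlation with motor impairment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .thresholds import GREATER_EQUAL, ThresholdModel

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "OptimalThresholdModel",
    "roc_optimal_threshold",
    "per_individual_thresholds",
    "auc_mann_whitney",
    "delong_auc_ci",
]


def auc_mann_whitney(counts: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability, ties counted half."""
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes; missing %s class"
                         % ("positive" if n_pos == 0 else "negative"))
    ranks = rankdata(counts)  # midranks handle ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def delong_auc_ci(counts: np.ndarray, labels: np.ndarray,
                  alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC and its DeLong (1988) confidence interval.

    Uses the placement-value formulation: V10[i] = P-hat(neg < pos_i) and
    V01[j] = P-hat(pos > neg_j), with ties counted half.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = counts[labels == 1]
    neg = counts[labels == 0]
    m, n = len(pos), len(neg)
    auc = auc_mann_whitney(counts, labels)
    # placements via midranks of the pooled sample
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = norm.ppf(1 - alpha / 2)
    return auc, float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se))


@dataclass(frozen=True)
class RocResult:
    """Fitted ROC summary: AUC with CI and the Youden-optimal operating point."""

    side: str
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    optimal_cutoff: float
    sensitivity_at_cut: float
    specificity_at_cut: float
    n_pos: int
    n_neg: int

    @property
    def threshold_model(self) -> ThresholdModel:
        return ThresholdModel(side=self.side, cutoff=self.optimal_cutoff,
                              comparison=GREATER_EQUAL)

    def predict(self, counts: np.ndarray) -> np.ndarray:
        from .thresholds import classify_threshold
        return classify_threshold(counts, self.threshold_model)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("side", "auc", "auc_ci_low", "auc_ci_high", "optimal_cutoff",
                 "sensitivity_at_cut", "specificity_at_cut", "n_pos", "n_neg")}

    def summary(self) -> str:
        lines = [
            "ROC-optimal threshold (%s side)" % self.side,
            "=" * 40,
            f"epochs           {self.n_pos + self.n_neg} "
            f"({self.n_pos} functional / {self.n_neg} non-functional)",
            f"AUC (95% CI)     {self.auc:.3f} "
            f"({self.auc_ci_low:.3f}, {self.auc_ci_high:.3f})",
            f"optimal cutoff   >= {self.optimal_cutoff:.1f} counts",
            f"sensitivity      {100 * self.sensitivity_at_cut:.2f}%",
            f"specificity      {100 * self.specificity_at_cut:.2f}%",
        ]
        return "\n".join(lines)


class OptimalThresholdModel:
    """Youden-optimal count threshold estimated from labelled epochs.

    Parameters
    ----------
    counts : array-like
        Per-epoch vector-magnitude activity counts (non-negative).
    labels : array-like of {0, 1}
        Dichotomized ground truth (1 = functional).
    side : str
        Which limb the counts belong to (carried into the fitted model).
    """

    def __init__(self, counts, labels, side: str = "affected") -> None:
        self.counts = np.asarray(counts, dtype=float)
        self.labels = np.asarray(labels, dtype=int)
        if self.counts.shape != self.labels.shape:
            raise ValueError("counts and labels must be aligned")
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be non-negative")
        self.side = side

    @classmethod
    def from_epochs(cls, table: pd.DataFrame, side: str) -> "OptimalThresholdModel":
        sub = table[(table["side"] == side) & (~table["excluded_wbm"])]
        return cls(sub["counts"].to_numpy(float),
                   sub["label"].to_numpy(int), side=side)

    def fit(self) -> RocResult:
        counts, labels = self.counts, self.labels
        pos = np.sort(counts[labels == 1])
        neg = np.sort(counts[labels == 0])
        if len(pos) == 0:
            raise ValueError("no functional (positive) epochs present")
        if len(neg) == 0:
            raise ValueError("no non-functional (negative) epochs present")

        # candidate cutoffs: observed values (classification uses ">="), plus
        # +inf for the all-negative decision
        cands = np.unique(counts)
        sens = 1.0 - np.searchsorted(pos, cands, side="left") / len(pos)
        spec = np.searchsorted(neg, cands, side="left") / len(neg)
        cands = np.append(cands, np.inf)
        sens = np.append(sens, 0.0)
        spec = np.append(spec, 1.0)
        youden = sens + spec
        best = int(np.argmax(youden))  # argmax returns the first (smallest cutoff)
        auc, lo, hi = delong_auc_ci(counts, labels)
        return RocResult(side=self.side, auc=auc, auc_ci_low=lo, auc_ci_high=hi,
                         optimal_cutoff=float(cands[best]),
                         sensitivity_at_cut=float(sens[best]),
                         specificity_at_cut=float(spec[best]),
                         n_pos=len(pos), n_neg=len(neg))


def roc_optimal_threshold(counts, labels, side: str = "affected") -> RocResult:
    """Functional wrapper around :class:`OptimalThresholdModel`."""
    return OptimalThresholdModel(counts, labels, side=side).fit()


def per_individual_thresholds(table: pd.DataFrame, side: str) -> dict[str, RocResult]:
    """One ROC fit per subject; subjects lacking a class are skipped."""
    out: dict[str, RocResult] = {}
    sub = table[(table["side"] == side) & (~table["excluded_wbm"])]
    for sid, grp in sub.groupby("subject_id"):
        labels = grp["label"].to_numpy(int)
        if labels.min() == labels.max():
            logger.warning("subject %s has a single class on the %s side; skipped",
                           sid, side)
            continue
        out[str(sid)] = roc_optimal_threshold(
            grp["counts"].to_numpy(float), labels, side=side)
    return out
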