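"""Performance evaluation: confusion measures, impairment strata, reports.

The five classification measures (sensitivity, specificity, accuracy,
positive and negative predictive value) are computed from exact confusion
tallies.  Per-subject threshold distributions are correlated with the
Fugl-Meyer score (Spearman), subjects are stratified into mild / moderate /
severe impairment, and the method-comparison grid mirrors the published
reporting layout (method x laterality x five measures, all methods sharing
one denominator set of epochs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .thresholds import bilateral_combine, bilateral_ground_truth

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionTable",
    "ConfusionReport",
    "confusion",
    "performance",
    "stratify_by_impairment",
    "threshold_fma_correlation",
    "descriptives_by_label",
    "method_comparison_report",
    "plot_per_subject_distributions",
]

MEASURES = ["sensitivity", "specificity", "accuracy", "ppv", "npv"]

# Fugl-Meyer impairment bands; the published bands leave 19-28 unassigned
# and we fold that gap into "severe" so the bands partition 0-66.
IMPAIRMENT_BANDS = {"mild": (43, 66), "moderate": (29, 42), "severe": (0, 28)}


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ConfusionReport:
    """The five measures as fractions; undefined measures are NaN."""

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float

    def as_percent(self) -> dict[str, float]:
        return {m: round(100 * getattr(self, m), 2) for m in MEASURES}


def confusion(predictions, truth) -> ConfusionTable:
    """Exact confusion tallies of boolean predictions against binary truth."""
    p = np.asarray(predictions, dtype=bool)
    t = np.asarray(truth, dtype=int)
    if p.shape != t.shape:
        raise ValueError("predictions and truth must be aligned")
    return ConfusionTable(tp=int(np.sum(p & (t == 1))),
                          fp=int(np.sum(p & (t == 0))),
                          tn=int(np.sum(~p & (t == 0))),
                          fn=int(np.sum(~p & (t == 1))))


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
        return float("nan")
    return num / den


def performance(table: ConfusionTable) -> ConfusionReport:
    """Sensitivity, specificity, accuracy, PPV and NPV from the tallies."""
    if table.total == 0:
        raise ValueError("empty confusion table")
    return ConfusionReport(
        sensitivity=_ratio(table.tp, table.tp + table.fn, "sensitivity"),
        specificity=_ratio(table.tn, table.tn + table.fp, "specificity"),
        accuracy=(table.tp + table.tn) / table.total,
        ppv=_ratio(table.tp, table.tp + table.fp, "ppv"),
        npv=_ratio(table.tn, table.tn + table.fn, "npv"),
    )


def stratify_by_impairment(fma_score: float) -> str:
    """Fugl-Meyer bands: mild 43-66, moderate 29-42, severe 0-28."""
    if not 0 <= fma_score <= 66:
        raise ValueError("FMA score must be in [0, 66]")
    for cat, (lo, hi) in IMPAIRMENT_BANDS.items():
        if lo <= fma_score <= hi:
            return cat
    raise AssertionError("unreachable: bands partition 0-66")


def threshold_fma_correlation(cutoffs, fma_scores) -> tuple[float, float]:
    """Spearman rank correlation of per-subject cutoffs with FMA scores."""
    c = np.asarray(cutoffs, dtype=float)
    f = np.asarray(fma_scores, dtype=float)
    if len(c) != len(f):
        raise ValueError("paired vectors required")
    if len(c) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(c) == 0 or np.ptp(f) == 0:
        warnings.warn("constant input; Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p = spearmanr(c, f)
    return float(rho), float(p)


def descriptives_by_label(table: pd.DataFrame) -> pd.DataFrame:
    """Count descriptives (n, median, Q1, Q3) per side and class label.

    Whole-body-movement epochs are reported as their own row per side;
    quartiles use linear interpolation.
    """
    if table.empty:
        raise ValueError("empty epoch table")
    df = table.copy()
    lab = df["label"].fillna(0).astype(int).to_numpy()
    df["class"] = np.where(df["excluded_wbm"], "wbm",
                           np.where(lab == 1, "functional", "non_functional"))
    rows = []
    for (side, cls), grp in df.groupby(["side", "class"]):
        c = grp["counts"].to_numpy(float)
        rows.append({"side": side, "class": cls, "n": len(c),
                     "median": float(np.percentile(c, 50)),
                     "q1": float(np.percentile(c, 25)),
                     "q3": float(np.percentile(c, 75))})
    return pd.DataFrame(rows).sort_values(["side", "class"]).reset_index(drop=True)


def _aligned_sides(table: pd.DataFrame) -> pd.DataFrame:
    """Epochs retained on both sides, joined on (subject, epoch_index)."""
    ret = table[~table["excluded_wbm"]]
    aff = ret[ret["side"] == "affected"]
    una = ret[ret["side"] == "unaffected"]
    merged = aff.merge(una, on=["subject_id", "epoch_index"],
                       suffixes=("_aff", "_una"))
    return merged


def method_comparison_report(table: pd.DataFrame,
                             methods: dict[str, dict],
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Performance grid (method x laterality x five measures, in %).

    ``methods`` maps a method name to ``{"affected": predictor,
    "unaffected": predictor}`` where a predictor is a callable mapping a
    counts array to boolean predictions (for the machine-learning method,
    pass precomputed predictions aligned to the retained epochs instead, as
    ``{"affected": array, ...}``).  The bilateral row is the conjunction of
    the two per-side classifications — never a third fitted model; methods
    whose bilateral rule uses different per-side components (the
    conventional >0 rule) may supply ``"bilateral_affected"`` /
    ``"bilateral_unaffected"`` predictors for it.  All methods are evaluated
    on identical retained epochs; per-subject distributions of every measure
    are returned alongside.
    """
    retained = {side: table[(table["side"] == side) & (~table["excluded_wbm"])]
                         .reset_index(drop=True)
                for side in ("affected", "unaffected")}
    merged = _aligned_sides(table)

    def _predict(spec_, side, sub: pd.DataFrame) -> np.ndarray:
        pred = spec_[side]
        if callable(pred):
            return np.asarray(pred(sub["counts"].to_numpy(float)), dtype=bool)
        pred = np.asarray(pred, dtype=bool)
        if len(pred) != len(sub):
            raise ValueError("prediction length does not match the shared "
                             "denominator epochs")
        return pred

    grid_rows, subj_rows = [], []
    for name, spec_ in methods.items():
        preds = {}
        for side in ("affected", "unaffected"):
            sub = retained[side]
            p = _predict(spec_, side, sub)
            bil_key = f"bilateral_{side}"
            bp_side = (_predict(spec_, bil_key, sub)
                       if bil_key in spec_ else p)
            preds[side] = pd.Series(bp_side, index=pd.MultiIndex.from_frame(
                sub[["subject_id", "epoch_index"]]))
            rep = performance(confusion(p, sub["label"].to_numpy(int)))
            grid_rows.append({"method": name, "laterality": side,
                              **rep.as_percent()})
            for sid, grp in sub.groupby("subject_id"):
                mask = sub["subject_id"] == sid
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = performance(confusion(p[mask.to_numpy()],
                                              grp["label"].to_numpy(int)))
                subj_rows.append({"method": name, "laterality": side,
                                  "subject_id": sid, **r.as_percent()})
        # bilateral: conjunction of the two unilateral predictions on epochs
        # retained on both sides
        key = pd.MultiIndex.from_frame(merged[["subject_id", "epoch_index"]])
        pa = preds["affected"].reindex(key).to_numpy(bool)
        pu = preds["unaffected"].reindex(key).to_numpy(bool)
        bp = bilateral_combine(pa, pu)
        bt = bilateral_ground_truth(merged["label_aff"].to_numpy(int),
                                    merged["label_una"].to_numpy(int))
        rep = performance(confusion(bp, bt))
        grid_rows.append({"method": name, "laterality": "bilateral",
                          **rep.as_percent()})
        for sid in merged["subject_id"].unique():
            m = (merged["subject_id"] == sid).to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = performance(confusion(bp[m], bt[m]))
            subj_rows.append({"method": name, "laterality": "bilateral",
                              "subject_id": sid, **r.as_percent()})
    return pd.DataFrame(grid_rows), pd.DataFrame(subj_rows)


def plot_per_subject_distributions(per_subject: pd.DataFrame,
                                   measure: str = "accuracy", ax=None):
    """Strip/box plot of a per-subject measure by method and laterality."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    keys, data = [], []
    for (method, lat), grp in per_subject.groupby(["method", "laterality"]):
        keys.append(f"{method}\n{lat}")
        data.append(grp[measure].dropna().to_numpy())
    ax.boxplot(data, tick_labels=keys)
    for i, vals in enumerate(data, start=1):
        ax.plot(np.full(len(vals), i) + np.random.default_rng(0).uniform(
            -0.08, 0.08, len(vals)), vals, "o", alpha=0.5, ms=3)
    ax.set_ylabel(f"{measure} (%)")
    ax.set_title(f"Per-subject {measure} by method and laterality")
    return ax
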