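"""Feature-based classification of 1-s epochs with LOSO logistic regression.

Raw IMU streams are median-filtered to suppress noise spikes, and a
low-pass filter separates the gravitational component from body
acceleration.  Per 1-s epoch (50 samples) a fixed schema of time- and
frequency-domain features is extracted from body acceleration, gyroscope,
gravity orientation and the barometric channel.  ``LosoLogitModel`` grid-
searches a regularized logistic regression under leave-one-subject-out
cross-validation with per-fold standardization, selects the hyperparameters
with the best mean validation accuracy, and refits on all data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, medfilt
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .io import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "FilteredStreams",
    "preprocess_signals",
    "extract_features",
    "build_feature_matrix",
    "LosoLogitModel",
    "LosoLogitResults",
    "default_grid",
]

SAMPLES_PER_EPOCH = 50
GRAVITY_CUTOFF_HZ = 0.25
MEDIAN_KERNEL = 3

META_COLUMNS = ["subject_id", "side", "epoch_index", "label"]


@dataclass
class FilteredStreams:
    """Spike-suppressed channels with gravity / body-acceleration split."""

    body: np.ndarray      # (n, 3) body acceleration in g
    gravity: np.ndarray   # (n, 3) gravitational component in g
    gyro: np.ndarray      # (n, 3) deg/s
    baro: np.ndarray      # (n,)
    sample_rate_hz: float = 50.0


def preprocess_signals(recording: Recording) -> FilteredStreams:
    """Median-filter every channel and separate gravity from body acceleration.

    Gravity is the zero-phase 2nd-order low-pass (0.25 Hz cutoff) of the
    spike-suppressed acceleration; body acceleration is the residual.
    """
    if not (np.all(np.isfinite(recording.accel))
            and np.all(np.isfinite(recording.gyro))
            and np.all(np.isfinite(recording.baro))):
        raise ValueError("recording contains non-finite samples")
    fs = recording.sample_rate_hz
    accel = np.column_stack([medfilt(recording.accel[:, i], MEDIAN_KERNEL)
                             for i in range(3)])
    gyro = np.column_stack([medfilt(recording.gyro[:, i], MEDIAN_KERNEL)
                            for i in range(3)])
    baro = medfilt(recording.baro, MEDIAN_KERNEL)
    b, a = butter(2, GRAVITY_CUTOFF_HZ / (fs / 2))
    gravity = np.column_stack([filtfilt(b, a, accel[:, i]) for i in range(3)])
    return FilteredStreams(body=accel - gravity, gravity=gravity,
                           gyro=gyro, baro=baro, sample_rate_hz=fs)


def _moments(x: np.ndarray, prefix: str) -> dict[str, float]:
    return {
        f"{prefix}_mean": float(np.mean(x)),
        f"{prefix}_std": float(np.std(x)),
        f"{prefix}_rms": float(np.sqrt(np.mean(x**2))),
        f"{prefix}_range": float(np.ptp(x)),
    }


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    # degenerate-variance convention: correlation of a constant channel is 0
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _spectral(x: np.ndarray, prefix: str, fs: float) -> dict[str, float]:
    """Unwindowed discrete spectrum of the 50-sample epoch (1 Hz bins)."""
    spec = np.abs(np.fft.rfft(x))**2 / len(x)
    power = spec[1:]  # bins 1..fs/2 Hz, DC excluded
    total = float(power.sum())
    if total == 0:
        return {f"{prefix}_dom_freq_hz": 0.0, f"{prefix}_dom_power": 0.0,
                f"{prefix}_power_1_10hz": 0.0, f"{prefix}_spec_entropy": 0.0}
    k = int(np.argmax(power))
    p = power / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {
        f"{prefix}_dom_freq_hz": float(k + 1),
        f"{prefix}_dom_power": float(power[k]),
        f"{prefix}_power_1_10hz": float(power[:10].sum()),
        f"{prefix}_spec_entropy": entropy,
    }


def extract_features(streams: FilteredStreams, start: int) -> dict[str, float]:
    """Feature vector for the 50-sample window beginning at ``start``.

    Fixed schema: moments of each body-acceleration and gyro axis and their
    magnitudes, inter-axis correlations of body acceleration, per-axis
    gravity means (posture proxy), spectral descriptors of the two
    magnitudes, and the barometric slope.
    """
    sl = slice(start, start + SAMPLES_PER_EPOCH)
    body = streams.body[sl]
    if len(body) != SAMPLES_PER_EPOCH:
        raise ValueError("feature window must contain exactly %d samples"
                         % SAMPLES_PER_EPOCH)
    gyro = streams.gyro[sl]
    gravity = streams.gravity[sl]
    baro = streams.baro[sl]
    body_mag = np.linalg.norm(body, axis=1)
    gyro_mag = np.linalg.norm(gyro, axis=1)

    feats: dict[str, float] = {}
    for i, ax in enumerate("xyz"):
        feats.update(_moments(body[:, i], f"body_{ax}"))
    feats.update(_moments(body_mag, "body_mag"))
    for i, ax in enumerate("xyz"):
        feats.update(_moments(gyro[:, i], f"gyro_{ax}"))
    feats.update(_moments(gyro_mag, "gyro_mag"))
    feats["body_corr_xy"] = _corr(body[:, 0], body[:, 1])
    feats["body_corr_xz"] = _corr(body[:, 0], body[:, 2])
    feats["body_corr_yz"] = _corr(body[:, 1], body[:, 2])
    for i, ax in enumerate("xyz"):
        feats[f"gravity_{ax}_mean"] = float(np.mean(gravity[:, i]))
    feats.update(_spectral(body_mag, "body_mag", streams.sample_rate_hz))
    feats.update(_spectral(gyro_mag, "gyro_mag", streams.sample_rate_hz))
    t = np.arange(SAMPLES_PER_EPOCH) / streams.sample_rate_hz
    feats["baro_slope"] = float(np.polyfit(t, baro, 1)[0])
    return feats


def build_feature_matrix(recording: Recording,
                         epoch_table: pd.DataFrame) -> pd.DataFrame:
    """Features for every retained epoch of one recording, joined to labels."""
    streams = preprocess_signals(recording)
    sub = epoch_table[(epoch_table["subject_id"] == recording.subject_id)
                      & (epoch_table["side"] == recording.side)
                      & (~epoch_table["excluded_wbm"])]
    rows = []
    for _, r in sub.iterrows():
        k = int(r["epoch_index"])
        f = extract_features(streams, k * SAMPLES_PER_EPOCH)
        f.update(subject_id=recording.subject_id, side=recording.side,
                 epoch_index=k, label=int(r["label"]))
        rows.append(f)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df[META_COLUMNS + [c for c in df.columns if c not in META_COLUMNS]]


def default_grid() -> list[dict]:
    """Penalty in {ridge, lasso} x 7 log-spaced strengths over 1e-3..1e3."""
    return [{"penalty": p, "C": float(c)}
            for p in ("l2", "l1") for c in np.logspace(-3, 3, 7)]


@dataclass
class LosoLogitResults:
    """Fitted LOSO logistic regression and its cross-validation report."""

    params: dict
    coefficients: pd.Series
    intercept: float
    feature_names: list[str]
    standardization: pd.DataFrame     # per-feature location/scale (full refit)
    cv_report: pd.DataFrame           # per-fold metrics of the selected params
    grid_trace: pd.DataFrame          # mean validation accuracy per grid point
    mean_cv_accuracy: float
    probability_cutoff: float = 0.5
    _scaler: StandardScaler = field(repr=False, default=None)
    _clf: LogisticRegression = field(repr=False, default=None)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        X = self._check_schema(features)
        return self._clf.predict_proba(self._scaler.transform(X))[:, 1]

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Functional iff predicted probability >= the 0.5 cutoff (inclusive)."""
        return self.predict_proba(features) >= self.probability_cutoff

    def _check_schema(self, features: pd.DataFrame) -> np.ndarray:
        cols = [c for c in features.columns if c not in META_COLUMNS]
        missing = sorted(set(self.feature_names) - set(cols))
        extra = sorted(set(cols) - set(self.feature_names))
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch; missing={missing} extra={extra}")
        return features[self.feature_names].to_numpy(float)

    def summary(self) -> str:
        top = self.coefficients.abs().sort_values(ascending=False).head(8)
        lines = [
            "LOSO logistic regression",
            "=" * 40,
            f"selected penalty   {self.params['penalty']}  C={self.params['C']:g}",
            f"folds              {len(self.cv_report)}",
            f"mean CV accuracy   {100 * self.mean_cv_accuracy:.2f}%",
            f"probability cutoff >= {self.probability_cutoff}",
            "largest |coefficients| (standardized scale):",
        ]
        for name in top.index:
            lines.append(f"  {name:<24s} {self.coefficients[name]:+.3f}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "params": self.params,
            "intercept": self.intercept,
            "coefficients": self.coefficients.to_dict(),
            "feature_names": self.feature_names,
            "standardization": self.standardization.to_dict(orient="list"),
            "mean_cv_accuracy": self.mean_cv_accuracy,
            "probability_cutoff": self.probability_cutoff,
            "grid_trace": self.grid_trace.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


class LosoLogitModel:
    """Grid-searched logistic regression under leave-one-subject-out CV.

    Parameters
    ----------
    features : DataFrame
        One row per retained epoch with ``subject_id``/``side``/``epoch_index``
        metadata, a binary ``label`` column and numeric feature columns.
    grid : list of dict, optional
        Hyperparameter grid ({"penalty", "C"}); defaults to
        :func:`default_grid`.  Ties in mean validation accuracy resolve to
        the earlier grid point.
    """

    def __init__(self, features: pd.DataFrame, grid: list[dict] | None = None):
        if features["subject_id"].nunique() < 2:
            raise ValueError("LOSO cross-validation needs at least two subjects")
        y = features["label"].to_numpy(int)
        if y.min() == y.max():
            raise ValueError("both classes must be present overall")
        self.features = features.reset_index(drop=True)
        self.grid = grid if grid is not None else default_grid()
        self.feature_names = [c for c in features.columns if c not in META_COLUMNS]

    def _make_clf(self, params: dict) -> LogisticRegression:
        l1_ratio = {"l1": 1.0, "l2": 0.0}[params["penalty"]]
        return LogisticRegression(l1_ratio=l1_ratio, C=params["C"],
                                  solver="liblinear", max_iter=2000)

    def fit(self) -> LosoLogitResults:
        X = self.features[self.feature_names].to_numpy(float)
        y = self.features["label"].to_numpy(int)
        groups = self.features["subject_id"].to_numpy()
        subjects = pd.unique(groups)

        trace_rows = []
        fold_reports: dict[int, pd.DataFrame] = {}
        for gi, params in enumerate(self.grid):
            rows = []
            for sid in subjects:
                test = groups == sid
                Xtr, ytr = X[~test], y[~test]
                if ytr.min() == ytr.max():
                    logger.warning("training folds for held-out %s contain a "
                                   "single class; fold excluded", sid)
                    continue
                scaler = StandardScaler().fit(Xtr)
                clf = self._make_clf(params).fit(scaler.transform(Xtr), ytr)
                pred = clf.predict_proba(scaler.transform(X[test]))[:, 1] >= 0.5
                yt = y[test]
                acc = float(np.mean(pred == yt))
                sens = float(np.mean(pred[yt == 1])) if (yt == 1).any() else np.nan
                spec = float(np.mean(~pred[yt == 0])) if (yt == 0).any() else np.nan
                rows.append({"subject_id": sid, "n_val": int(test.sum()),
                             "accuracy": acc, "sensitivity": sens,
                             "specificity": spec,
                             "scaler_mean_first": float(scaler.mean_[0]),
                             "scaler_scale_first": float(scaler.scale_[0])})
            report = pd.DataFrame(rows)
            mean_acc = float(report["accuracy"].mean()) if len(report) else np.nan
            trace_rows.append({"grid_index": gi, **params,
                               "mean_val_accuracy": mean_acc})
            fold_reports[gi] = report

        trace = pd.DataFrame(trace_rows)
        best = int(trace["mean_val_accuracy"].idxmax())  # first max wins ties
        best_params = self.grid[best]

        scaler = StandardScaler().fit(X)
        clf = self._make_clf(best_params).fit(scaler.transform(X), y)
        coef = pd.Series(clf.coef_[0], index=self.feature_names)
        standardization = pd.DataFrame(
            {"feature": self.feature_names, "location": scaler.mean_,
             "scale": scaler.scale_}).set_index("feature")
        return LosoLogitResults(
            params=dict(best_params), coefficients=coef,
            intercept=float(clf.intercept_[0]),
            feature_names=list(self.feature_names),
            standardization=standardization,
            cv_report=fold_reports[best], grid_trace=trace,
            mean_cv_accuracy=float(trace.loc[best, "mean_val_accuracy"]),
            _scaler=scaler, _clf=clf)


def fit_logreg_loso(features: pd.DataFrame,
                    grid: list[dict] | None = None) -> LosoLogitResults:
    """Functional wrapper around :class:`LosoLogitModel`."""
    return LosoLogitModel(features, grid=grid).fit()
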