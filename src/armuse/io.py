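"""Recordings, frame-level ground-truth labels, and 1-s epoch tables.

Ground truth for arm use is annotated on video frames (30 fps) with a
movement-primitive taxonomy; sensor data run at 50 Hz.  This module collapses
the primitive taxonomy to the three analysis classes (functional,
non-functional, whole-body movement), resamples the 30 fps label track onto
the 50 Hz sample clock, aggregates samples into 1-s epochs with a modal-label
rule, and removes whole-body-movement epochs from the classification ground
truth.  Epoch tables are plain pandas DataFrames with a fixed schema so they
can round-trip through CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FUNCTIONAL",
    "NON_FUNCTIONAL",
    "WBM",
    "EPOCH_COLUMNS",
    "Recording",
    "FrameLabelTrack",
    "collapse_taxonomy",
    "resample_labels",
    "epochize",
    "exclude_wbm",
    "read_epoch_table",
    "write_epoch_table",
]

FUNCTIONAL = "functional"
NON_FUNCTIONAL = "non_functional"
WBM = "wbm"
LABEL_ALPHABET = (FUNCTIONAL, NON_FUNCTIONAL, WBM)

# movement-primitive taxonomy -> analysis class
_TAXONOMY = {
    "reach": FUNCTIONAL,
    "reposition": FUNCTIONAL,
    "transport": FUNCTIONAL,
    "communication_gesture": FUNCTIONAL,
    "stabilize": NON_FUNCTIONAL,
    "idle": NON_FUNCTIONAL,
    "gait": WBM,
    "transfer": WBM,
    "secondary_wrist_movement": WBM,
}

EPOCH_COLUMNS = ["subject_id", "side", "epoch_index", "counts", "label", "excluded_wbm"]

RECORDING_COLUMNS = ["subject_id", "side", "t_s", "ax_g", "ay_g", "az_g",
                     "gx_dps", "gy_dps", "gz_dps", "baro"]


@dataclass
class Recording:
    """One wrist sensor stream: 50 Hz tri-axial accel (g), gyro (deg/s), baro."""

    subject_id: str
    side: str
    t: np.ndarray
    accel: np.ndarray  # (n, 3) in g
    gyro: np.ndarray   # (n, 3) in deg/s
    baro: np.ndarray   # (n,)
    sample_rate_hz: float = 50.0

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (self.accel.shape == (n, 3) and self.gyro.shape == (n, 3)
                and self.baro.shape == (n,)):
            raise ValueError("all channels must share the same length")
        if n > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.sample_rate_hz, atol=1e-6):
                raise ValueError("sample spacing must be 1/%.0f s" % self.sample_rate_hz)

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.sample_rate_hz

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "subject_id": self.subject_id, "side": self.side, "t_s": self.t,
            "ax_g": self.accel[:, 0], "ay_g": self.accel[:, 1], "az_g": self.accel[:, 2],
            "gx_dps": self.gyro[:, 0], "gy_dps": self.gyro[:, 1], "gz_dps": self.gyro[:, 2],
            "baro": self.baro,
        })
        return df[RECORDING_COLUMNS]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Recording":
        missing = set(RECORDING_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"recording is missing columns: {sorted(missing)}")
        return cls(
            subject_id=str(df["subject_id"].iloc[0]),
            side=str(df["side"].iloc[0]),
            t=df["t_s"].to_numpy(float),
            accel=df[["ax_g", "ay_g", "az_g"]].to_numpy(float),
            gyro=df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(float),
            baro=df["baro"].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path) -> "Recording":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class FrameLabelTrack:
    """Per-video-frame class labels at 30 fps for one side."""

    subject_id: str
    side: str
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(LABEL_ALPHABET)
        if bad:
            raise ValueError(f"labels outside alphabet {LABEL_ALPHABET}: {sorted(bad)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_id, "side": self.side,
            "frame_index": np.arange(len(self.labels)), "label": self.labels,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrameLabelTrack":
        df = pd.read_csv(path).sort_values("frame_index")
        return cls(subject_id=str(df["subject_id"].iloc[0]),
                   side=str(df["side"].iloc[0]),
                   labels=df["label"].to_numpy(object))


def collapse_taxonomy(primitive: str) -> str:
    """Map a movement primitive onto {functional, non_functional, wbm}.

    Object-directed primitives (reach, reposition, transport, communication
    gestures) are functional; stabilize and idle are non-functional; gait,
    transfers and wrist movement secondary to other body parts are
    whole-body movement.
    """
    try:
        return _TAXONOMY[primitive]
    except KeyError:
        raise ValueError(f"unknown movement primitive: {primitive!r}") from None


def resample_labels(track: FrameLabelTrack, target_rate_hz: float = 50.0) -> np.ndarray:
    """Resample a 30 fps label track to the sensor sample clock.

    The sample at time t takes the label of the video frame covering t,
    i.e. frame floor(t * frame_rate) — a causal nearest-preceding-frame
    mapping that never interpolates categorical labels.
    """
    if track.frame_rate != 30.0:
        raise ValueError("label tracks are defined at 30 fps")
    if len(track.labels) == 0:
        raise ValueError("empty label track")
    duration = len(track.labels) / track.frame_rate
    n_out = int(round(duration * target_rate_hz))
    t = np.arange(n_out) / target_rate_hz
    idx = np.floor(t * track.frame_rate).astype(int)
    idx = np.minimum(idx, len(track.labels) - 1)
    return track.labels[idx]


def epochize(sample_labels: np.ndarray, counts: np.ndarray, subject_id: str,
             side: str, samples_per_epoch: int = 50) -> pd.DataFrame:
    """Aggregate per-sample labels and per-epoch counts into an epoch table.

    Each 1-s epoch takes the modal class of its samples.  Epochs whose modal
    class is whole-body movement are flagged ``excluded_wbm`` (their binary
    label is left missing); ties between functional and non-functional break
    toward functional, favouring sensitivity for sparse functional movement.
    A trailing partial window is dropped.
    """
    sample_labels = np.asarray(sample_labels, dtype=object)
    counts = np.asarray(counts, dtype=float)
    n_epochs = len(sample_labels) // samples_per_epoch
    if len(sample_labels) % samples_per_epoch:
        logger.info("dropping trailing partial window of %d samples",
                    len(sample_labels) % samples_per_epoch)
    if n_epochs != len(counts):
        raise ValueError(
            f"label track covers {n_epochs} epochs but {len(counts)} counts given")

    rows = []
    for k in range(n_epochs):
        window = sample_labels[k * samples_per_epoch:(k + 1) * samples_per_epoch]
        n_f = int(np.sum(window == FUNCTIONAL))
        n_n = int(np.sum(window == NON_FUNCTIONAL))
        n_w = int(np.sum(window == WBM))
        if n_w > max(n_f, n_n):
            rows.append((subject_id, side, k, counts[k], pd.NA, True))
        else:
            rows.append((subject_id, side, k, counts[k], int(n_f >= n_n), False))
    df = pd.DataFrame(rows, columns=EPOCH_COLUMNS)
    df["label"] = df["label"].astype("Int64")
    return df


def exclude_wbm(table: pd.DataFrame) -> pd.DataFrame:
    """Drop whole-body-movement epochs from the classification ground truth."""
    flagged = int(table["excluded_wbm"].sum())
    out = table.loc[~table["excluded_wbm"].astype(bool)].reset_index(drop=True)
    if out.empty and flagged:
        logger.warning("all %d epochs were whole-body movement; table is empty", flagged)
    return out


def write_epoch_table(table: pd.DataFrame, path) -> None:
    table[EPOCH_COLUMNS].to_csv(path, index=False)


def read_epoch_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EPOCH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"epoch table is missing columns: {sorted(missing)}")
    df["label"] = df["label"].astype("Int64")
    df["excluded_wbm"] = df["excluded_wbm"].astype(bool)
    return df
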