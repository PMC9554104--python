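"""Synthetic two-wrist cohorts with the statistical structure of real data.

The generator emulates a home-recorded stroke cohort: per-subject functional
prevalence (low and highly variable on the affected side, higher on the
unaffected side), whole-body-movement segments that inflate both wrists'
counts, and class-conditional activity-count distributions modelled as
zero-inflated log-normals calibrated to published per-class count quartiles
and operating points.  Two modes are supported:

``counts`` mode
    draws labelled per-epoch activity counts directly from the
    class-conditional mixtures (fast; used for threshold analyses), and

``raw`` mode
    synthesises 50 Hz IMU signals (gravity plus band-limited movement bursts
    plus sensor noise) together with a 30 fps frame-label track, so the full
    signal pipeline (counts, features, classifiers) can run end to end.

Impairment couples to movement intensity: the affected-side functional
log-location shifts linearly with the Fugl-Meyer deficit, reflecting the
lower acceleration magnitudes of hemiparetic movement.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.signal import butter, lfilter
from scipy.stats import norm

from .io import (EPOCH_COLUMNS, FUNCTIONAL, NON_FUNCTIONAL, WBM,
                 FrameLabelTrack, Recording)

__all__ = [
    "SubjectProfile",
    "ClassIntensity",
    "ClassIntensityModel",
    "SimConfig",
    "calibrate_from_quartiles",
    "calibrate_from_cdf_points",
    "default_intensity_model",
    "generate_subject_profiles",
    "generate_counts_sequence",
    "generate_raw_recording",
    "generate_cohort",
]

AFFECTED = "affected"
UNAFFECTED = "unaffected"

# cohort-level calibration constants (per-subject functional prevalence and
# Fugl-Meyer range observed in home recordings of stroke survivors)
PREVALENCE_AFFECTED = (0.25, 0.194)
PREVALENCE_UNAFFECTED = (0.46, 0.119)
PREVALENCE_CLIP = (0.01, 0.95)
WBM_FRACTION = (0.50, 0.15)
WBM_CLIP = (0.0, 0.9)
FMA_RANGE = (16, 65)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SubjectProfile:
    """Clinical and behavioural profile of one simulated subject."""

    subject_id: str
    fma_score: int
    affected_side: str  # {"left", "right"}
    functional_prevalence_affected: float
    functional_prevalence_unaffected: float
    wbm_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.fma_score <= 66:
            raise ConfigError("fma_score must be in [0, 66]")
        for v in (self.functional_prevalence_affected,
                  self.functional_prevalence_unaffected, self.wbm_fraction):
            if not 0.0 <= v <= 1.0:
                raise ConfigError("prevalences and wbm_fraction must be in [0, 1]")

    def prevalence(self, side: str) -> float:
        return (self.functional_prevalence_affected if side == AFFECTED
                else self.functional_prevalence_unaffected)


@dataclass(frozen=True)
class ClassIntensity:
    """Zero-inflated log-normal intensity of one (side, class) cell."""

    zero_mass: float
    log_location: float
    log_scale: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_mass <= 1.0:
            raise ConfigError("zero_mass must be in [0, 1]")
        if self.log_scale <= 0:
            raise ConfigError("log_scale must be positive")

    def sample(self, rng: np.random.Generator, n: int,
               log_shift: float = 0.0) -> np.ndarray:
        zero = rng.random(n) < self.zero_mass
        vals = rng.lognormal(self.log_location + log_shift, self.log_scale, n)
        return np.where(zero, 0.0, vals)

    def cdf(self, c: np.ndarray, log_shift: float = 0.0) -> np.ndarray:
        """P(X <= c); the zero atom sits at 0."""
        c = np.asarray(c, dtype=float)
        cont = np.zeros_like(c)
        pos = c > 0
        cont[pos] = norm.cdf((np.log(c[pos]) - self.log_location - log_shift)
                             / self.log_scale)
        return np.where(c < 0, 0.0, self.zero_mass + (1 - self.zero_mass) * cont)


def calibrate_from_quartiles(q1: float, median: float, q3: float,
                             zero_mass: float) -> ClassIntensity:
    """Fit (log_location, log_scale) so the mixture quartiles match.

    The zero atom occupies the lowest ``zero_mass`` of probability, so the
    mixture quantile p corresponds to the continuous-part quantile
    (p - zero_mass) / (1 - zero_mass); requires all three quartiles > 0.
    """
    if min(q1, median, q3) <= 0:
        raise ConfigError("quartile calibration requires positive quartiles")
    p = (np.array([0.25, 0.5, 0.75]) - zero_mass) / (1 - zero_mass)
    if p[0] <= 0:
        raise ConfigError("zero_mass too large for Q1 > 0")
    zq = norm.ppf(p)
    log_scale = (np.log(q3) - np.log(q1)) / (zq[2] - zq[0])
    log_location = np.log(median) - log_scale * zq[1]
    return ClassIntensity(zero_mass, float(log_location), float(log_scale))


def calibrate_from_cdf_points(points: list[tuple[float, float]]) -> ClassIntensity:
    """Fit (zero_mass, log_location, log_scale) to three CDF constraints.

    ``points`` is a list of (count value c, P(X <= c)) pairs.  Used for
    median-zero classes where the quartile rule is degenerate: the published
    upper quartile and the specificities of known thresholds each pin one
    point of the class CDF.
    """
    if len(points) != 3:
        raise ConfigError("need exactly three CDF points")

    def residual(params):
        z, mu, log_sg = params
        sg = np.exp(log_sg)
        return [z + (1 - z) * norm.cdf((np.log(c) - mu) / sg) - p
                for c, p in points]

    sol, info, ier, msg = optimize.fsolve(residual, [0.6, 3.0, 0.2],
                                          full_output=True)
    if ier != 1 or not 0 < sol[0] < 1:
        raise ConfigError(f"CDF-point calibration failed: {msg}")
    return ClassIntensity(float(sol[0]), float(sol[1]), float(np.exp(sol[2])))


@dataclass(frozen=True)
class ClassIntensityModel:
    """Class-conditional count intensities per side, plus impairment coupling.

    ``fma_coupling_log`` is the total log-location shift of affected-side
    functional intensity across the simulated Fugl-Meyer range: a subject at
    the bottom of the range moves with exp(-coupling/2) times the median
    intensity of a subject at the centre.
    """

    functional_affected: ClassIntensity
    functional_unaffected: ClassIntensity
    nonfunctional_affected: ClassIntensity
    nonfunctional_unaffected: ClassIntensity
    wbm_affected: ClassIntensity
    wbm_unaffected: ClassIntensity
    fma_coupling_log: float = 0.6
    fma_reference: float = 40.5

    def cell(self, side: str, label: str) -> ClassIntensity:
        key = {FUNCTIONAL: "functional", NON_FUNCTIONAL: "nonfunctional",
               WBM: "wbm"}[label] + "_" + side
        return getattr(self, key)

    def log_shift(self, side: str, label: str, fma_score: float) -> float:
        if side == AFFECTED and label == FUNCTIONAL:
            span = FMA_RANGE[1] - FMA_RANGE[0]
            return self.fma_coupling_log * (fma_score - self.fma_reference) / span
        return 0.0


def default_intensity_model() -> ClassIntensityModel:
    """Intensity model calibrated to the published per-class count statistics.

    Functional and WBM cells use the printed quartiles directly; the
    median-zero non-functional cells are solved from the printed upper
    quartile together with the specificities of the conventional (>2) and
    optimal (>=20.1 / >=38.6) thresholds, which are three points of the
    non-functional count CDF.
    """
    return ClassIntensityModel(
        functional_affected=calibrate_from_quartiles(37, 78.9, 139, zero_mass=0.05),
        functional_unaffected=calibrate_from_quartiles(61, 118.0, 191, zero_mass=0.05),
        nonfunctional_affected=calibrate_from_cdf_points(
            [(2, 0.6368), (16, 0.75), (20.1, 0.7760)]),
        nonfunctional_unaffected=calibrate_from_cdf_points(
            [(2, 0.5756), (35, 0.75), (38.6, 0.7629)]),
        wbm_affected=calibrate_from_quartiles(21, 43.8, 72, zero_mass=0.02),
        wbm_unaffected=calibrate_from_quartiles(34, 65.4, 122, zero_mass=0.02),
    )


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings."""

    n_subjects: int = 14
    duration_s: int = 600
    seed: int = 0
    mode: str = "counts"  # {"counts", "raw"}
    sample_rate_hz: float = 50.0
    label_rate_fps: float = 30.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.duration_s < 10:
            raise ConfigError("duration_s must be >= 10")
        if self.mode not in ("counts", "raw"):
            raise ConfigError("mode must be 'counts' or 'raw'")
        if self.sample_rate_hz != 50.0 or self.label_rate_fps != 30.0:
            raise ConfigError("sample clock is fixed at 50 Hz / 30 fps")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        return cls(**json.loads(Path(path).read_text()))


def _subject_rng(config: SimConfig, subject_id: str, stream: int = 0) -> np.random.Generator:
    # per-subject seeded stream: subjects are reproducible independently of
    # cohort size or generation order
    tag = zlib.crc32(subject_id.encode())
    return np.random.default_rng([config.seed, tag, stream])


def _clip_normal(rng, mean, sd, lo, hi, size=None):
    return np.clip(rng.normal(mean, sd, size), lo, hi)


def generate_subject_profiles(config: SimConfig) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles.

    Functional prevalences are normal draws clipped to [0.01, 0.95]
    (affected mean 0.25 SD 0.194; unaffected mean 0.46 SD 0.119); the
    whole-body-movement fraction is clipped to [0, 0.9]; Fugl-Meyer scores
    are uniform over the observed 16-65 range.
    """
    profiles = []
    for i in range(config.n_subjects):
        sid = f"S{i:03d}"
        rng = _subject_rng(config, sid)
        profiles.append(SubjectProfile(
            subject_id=sid,
            fma_score=int(rng.integers(FMA_RANGE[0], FMA_RANGE[1] + 1)),
            affected_side="left" if rng.random() < 0.5 else "right",
            functional_prevalence_affected=float(_clip_normal(
                rng, *PREVALENCE_AFFECTED, *PREVALENCE_CLIP)),
            functional_prevalence_unaffected=float(_clip_normal(
                rng, *PREVALENCE_UNAFFECTED, *PREVALENCE_CLIP)),
            wbm_fraction=float(_clip_normal(rng, *WBM_FRACTION, *WBM_CLIP)),
        ))
    return profiles


def profiles_to_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in profiles])


def _draw_epoch_labels(rng, n, prevalence, wbm_fraction):
    u = rng.random(n)
    labels = np.where(u < wbm_fraction, WBM,
                      np.where(rng.random(n) < prevalence, FUNCTIONAL,
                               NON_FUNCTIONAL))
    return labels


def generate_counts_sequence(profile: SubjectProfile,
                             intensity: ClassIntensityModel,
                             config: SimConfig) -> pd.DataFrame:
    """Labelled per-epoch activity counts for both wrists of one subject.

    Per epoch, the class label is whole-body movement with probability
    ``wbm_fraction`` and otherwise functional with the side's prevalence;
    the count is then drawn from that (side, class) intensity mixture.
    Returns an epoch table with the standard schema.
    """
    if config.mode != "counts":
        raise ConfigError("generate_counts_sequence requires mode='counts'")
    frames = []
    n = int(config.duration_s)
    for stream, side in enumerate((AFFECTED, UNAFFECTED)):
        rng = _subject_rng(config, profile.subject_id, stream=1 + stream)
        labels = _draw_epoch_labels(rng, n, profile.prevalence(side),
                                    profile.wbm_fraction)
        counts = np.empty(n)
        for lab in (FUNCTIONAL, NON_FUNCTIONAL, WBM):
            mask = labels == lab
            cell = intensity.cell(side, lab)
            shift = intensity.log_shift(side, lab, profile.fma_score)
            counts[mask] = cell.sample(rng, int(mask.sum()), log_shift=shift)
        df = pd.DataFrame({
            "subject_id": profile.subject_id, "side": side,
            "epoch_index": np.arange(n), "counts": counts,
            "label": pd.array(np.where(labels == WBM, pd.NA,
                                       (labels == FUNCTIONAL).astype("float")),
                              dtype="Int64"),
            "excluded_wbm": labels == WBM,
        })
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[EPOCH_COLUMNS]


def _bandlimited_noise(rng, n, fs, lo=0.5, hi=5.0):
    b, a = butter(2, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    x = lfilter(b, a, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


# conversion from a target epoch count to a burst amplitude in g; chosen so
# typical functional epochs (~80 counts) produce ~0.3 g bursts, comfortably
# above the dead-band and below saturation
AMP_PER_COUNT_G = 0.004
GYRO_DPS_PER_G = 60.0
WBM_OSC_HZ = 1.8
WBM_OSC_AMP_G = 0.15
ACCEL_NOISE_G = 0.005
GYRO_NOISE_DPS = 0.2


def generate_raw_recording(profile: SubjectProfile, config: SimConfig,
                           intensity: ClassIntensityModel | None = None,
                           amplitude_scale: float = 1.0,
                           ) -> tuple[dict[str, Recording], dict[str, FrameLabelTrack]]:
    """Synthesize 50 Hz IMU signals and 30 fps label tracks for both wrists.

    Acceleration is a slowly wandering unit-gravity vector plus band-limited
    (0.5-5 Hz) movement bursts whose amplitude scales with the epoch's
    class-conditional intensity, plus white sensor noise.  Whole-body
    movement adds a common-mode oscillation to both wrists.  Gyro bursts are
    proportional to the acceleration bursts; the barometric channel is a slow
    random walk.  ``amplitude_scale`` multiplies all movement (not gravity or
    sensor noise), which makes monotonicity of downstream counts testable.
    """
    if config.mode != "raw":
        raise ConfigError("generate_raw_recording requires mode='raw'")
    intensity = intensity or default_intensity_model()
    n_epochs = int(config.duration_s)
    if n_epochs < 1:
        raise ConfigError("duration too short for one epoch")
    fs = config.sample_rate_hz
    n = int(n_epochs * fs)
    spe = int(fs)  # samples per epoch
    fpe = int(config.label_rate_fps)  # frames per epoch

    rng_wbm = _subject_rng(config, profile.subject_id, stream=9)
    # common-mode whole-body oscillation phase shared by both wrists
    wbm_phase = rng_wbm.uniform(0, 2 * np.pi)

    recordings: dict[str, Recording] = {}
    tracks: dict[str, FrameLabelTrack] = {}
    t = np.arange(n) / fs
    for stream, side in enumerate((AFFECTED, UNAFFECTED)):
        rng = _subject_rng(config, profile.subject_id, stream=5 + stream)
        labels = _draw_epoch_labels(rng, n_epochs, profile.prevalence(side),
                                    profile.wbm_fraction)
        # per-epoch burst amplitude from the class intensity mixture
        target = np.empty(n_epochs)
        for lab in (FUNCTIONAL, NON_FUNCTIONAL, WBM):
            mask = labels == lab
            cell = intensity.cell(side, lab)
            shift = intensity.log_shift(side, lab, profile.fma_score)
            target[mask] = cell.sample(rng, int(mask.sum()), log_shift=shift)
        amp = np.repeat(target * AMP_PER_COUNT_G * amplitude_scale, spe)

        # slowly wandering orientation of the gravity vector
        tilt = lfilter(*butter(2, 0.02 / (fs / 2)), rng.standard_normal(n)) * 5.0
        roll = lfilter(*butter(2, 0.02 / (fs / 2)), rng.standard_normal(n)) * 5.0
        gravity = np.column_stack([np.sin(tilt), np.sin(roll) * np.cos(tilt),
                                   np.cos(roll) * np.cos(tilt)])

        # movement bursts distributed across axes with per-epoch weights
        burst = _bandlimited_noise(rng, n, fs)
        w = rng.random((n_epochs, 3)) + 0.2
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        weights = np.repeat(w, spe, axis=0)
        movement = weights * (amp * burst)[:, None]

        wbm_mask = np.repeat(labels == WBM, spe).astype(float)
        wbm_osc = (WBM_OSC_AMP_G * amplitude_scale * wbm_mask
                   * np.sin(2 * np.pi * WBM_OSC_HZ * t + wbm_phase))
        accel = gravity + movement + rng.standard_normal((n, 3)) * ACCEL_NOISE_G
        accel[:, 2] += wbm_osc

        gyro = (weights * (amp * _bandlimited_noise(rng, n, fs))[:, None]
                * GYRO_DPS_PER_G
                + rng.standard_normal((n, 3)) * GYRO_NOISE_DPS)
        baro = 950.0 + np.cumsum(rng.standard_normal(n)) * 0.002 \
            + rng.standard_normal(n) * 0.05

        recordings[side] = Recording(profile.subject_id, side, t.copy(),
                                     accel, gyro, baro)
        tracks[side] = FrameLabelTrack(profile.subject_id, side,
                                       np.repeat(labels, fpe))
    return recordings, tracks


def generate_cohort(config: SimConfig,
                    intensity: ClassIntensityModel | None = None,
                    ) -> tuple[list[SubjectProfile], pd.DataFrame]:
    """Profiles plus a pooled counts-mode epoch table for the whole cohort."""
    intensity = intensity or default_intensity_model()
    profiles = generate_subject_profiles(config)
    tables = [generate_counts_sequence(p, intensity, config) for p in profiles]
    return profiles, pd.concat(tables, ignore_index=True)
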