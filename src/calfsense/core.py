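"""Core domain types for collar-mounted six-axis IMU recordings.

A recording holds triaxial acceleration (g) and angular velocity (deg/s)
sampled at a fixed rate (25 Hz by default, the collar's native rate).
Behavior ground truth lives in a parallel :class:`AnnotationTrack` with
three tiers:

``action``
    feeding-related behaviors that can co-occur with a posture
    (natural suckling, feeding, rumination),
``state``
    mutually exclusive postures covering all time (lying, standing),
``event``
    short transients (coughing, < 2 s).

The orientation-robust magnitude channels

.. math::

    A_m = \\sqrt{a_x^2 + a_y^2 + a_z^2}, \\qquad
    G_m = \\sqrt{g_x^2 + g_y^2 + g_z^2}

are attached on demand and used both for feature extraction and for the
acceleration-peak anchoring of cough event windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ShapeError, VocabularyError

#: Channel order used throughout the pipeline (feature names, window slices).
AXIS_CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")
ALL_CHANNELS = AXIS_CHANNELS + ("am", "gm")

#: Ethogram vocabulary per tier.
ACTION_BEHAVIORS = ("natural_suckling", "feeding", "rumination")
STATE_BEHAVIORS = ("lying", "standing")
EVENT_BEHAVIORS = ("coughing",)
CORE_VOCABULARY = ACTION_BEHAVIORS + STATE_BEHAVIORS + EVENT_BEHAVIORS

TIERS = ("action", "state", "event")

RECORDING_COLUMNS = ("t", "calf_id") + AXIS_CHANNELS
ANNOTATION_COLUMNS = ("calf_id", "behavior", "tier", "start_s", "end_s")

#: Maximum allowed duration of an event-tier interval, seconds.
MAX_EVENT_DURATION_S = 2.0


@dataclass(frozen=True)
class SensorConfig:
    """Sensor geometry and acquisition settings.

    Parameters
    ----------
    fs : float
        Sampling frequency in Hz.
    accel_scale : float
        Full-scale accelerometer range in g; samples beyond it are rejected.
    gyro_scale : float
        Full-scale gyroscope range in deg/s.
    nodding_axis : str
        Gyroscope axis aligned with the head-nodding rotation (the axis
        interrogated for suckling periodicity); one of ``x``, ``y``, ``z``.
    """

    fs: float = 25.0
    accel_scale: float = 4.0
    gyro_scale: float = 500.0
    nodding_axis: str = "y"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.accel_scale <= 0 or self.gyro_scale <= 0:
            raise ValueError("sensor scales must be positive")
        if self.nodding_axis not in ("x", "y", "z"):
            raise ValueError("nodding_axis must be one of x, y, z")

    @property
    def nodding_channel(self) -> str:
        """Gyroscope channel name of the nodding rotation axis."""
        return "g" + self.nodding_axis


@dataclass
class IMURecording:
    """One calf's six-axis time series with optional magnitude channels.

    ``t`` is seconds since recording start and must advance by 1/fs within
    a 10 % tolerance. All per-channel arrays share one length.
    """

    calf_id: str
    fs: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    am: np.ndarray | None = None
    gm: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrays = [getattr(self, c) for c in AXIS_CHANNELS]
        n = len(self.t)
        if n < 1:
            raise IntegrityError("recording must contain at least one sample")
        if any(len(a) != n for a in arrays):
            raise ShapeError("all channels must share the timestamp length")
        if np.any(self.t < 0):
            raise IntegrityError("timestamps must be nonnegative")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise IntegrityError("timestamps must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.fs) > 0.1 / self.fs):
                raise IntegrityError(
                    "timestamp spacing deviates from 1/fs beyond tolerance"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        """Span between first and last sample, (N-1)/fs for a regular grid."""
        return float(self.t[-1] - self.t[0])

    def channel(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            raise ShapeError(f"channel {name!r} not populated (run attach_magnitudes)")
        return arr

    def stacked(self, channels: tuple[str, ...] = ALL_CHANNELS) -> np.ndarray:
        """Return an (N, n_channels) array in the given channel order."""
        return np.column_stack([self.channel(c) for c in channels])

    def validate_scales(self, config: SensorConfig) -> None:
        for c in ("ax", "ay", "az"):
            if np.any(np.abs(getattr(self, c)) > config.accel_scale):
                raise IntegrityError(f"{c} exceeds accel_scale {config.accel_scale} g")
        for c in ("gx", "gy", "gz"):
            if np.any(np.abs(getattr(self, c)) > config.gyro_scale):
                raise IntegrityError(f"{c} exceeds gyro_scale {config.gyro_scale} deg/s")


@dataclass(frozen=True)
class Interval:
    """One annotated behavior bout."""

    behavior: str
    tier: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AnnotationTrack:
    """Per-calf behavior intervals on action, state and event tiers."""

    calf_id: str
    intervals: list[Interval] = field(default_factory=list)
    vocabulary: tuple[str, ...] = CORE_VOCABULARY

    def __post_init__(self) -> None:
        for iv in self.intervals:
            self._check_interval(iv)
        for tier in ("action", "state", "event"):
            self._check_overlaps(tier)

    def _check_interval(self, iv: Interval) -> None:
        if iv.tier not in TIERS:
            raise VocabularyError(f"unknown tier {iv.tier!r}")
        if iv.behavior not in self.vocabulary:
            raise VocabularyError(f"unknown behavior {iv.behavior!r}")
        if iv.end_s <= iv.start_s:
            raise IntegrityError(f"interval end must exceed start: {iv}")
        if iv.tier == "event" and iv.duration_s >= MAX_EVENT_DURATION_S:
            raise IntegrityError(
                f"event interval must last less than {MAX_EVENT_DURATION_S} s: {iv}"
            )

    def _check_overlaps(self, tier: str) -> None:
        ivs = sorted(self.tier_intervals(tier), key=lambda iv: iv.start_s)
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s:
                raise IntegrityError(
                    f"overlapping {tier}-tier intervals: {a} and {b}"
                )

    def tier_intervals(self, tier: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.tier == tier]

    def add(self, interval: Interval) -> None:
        self._check_interval(interval)
        self.intervals.append(interval)
        self._check_overlaps(interval.tier)


def magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Element-wise Euclidean norm of three equal-length series."""
    x, y, z = np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    if not (x.shape == y.shape == z.shape):
        raise ShapeError("magnitude requires three equal-length series")
    return np.sqrt(x * x + y * y + z * z)


def attach_magnitudes(rec: IMURecording) -> IMURecording:
    """Return a recording with Am and Gm populated (idempotent)."""
    return replace(
        rec,
        am=magnitude(rec.ax, rec.ay, rec.az),
        gm=magnitude(rec.gx, rec.gy, rec.gz),
    )


def read_recording(
    path, config: SensorConfig | None = None, clip_to_scale: bool = False
) -> IMURecording:
    """Read a recording CSV (columns t, calf_id, ax..az, gx..gz).

    Rows violating the sensor full-scale bounds raise ``IntegrityError``
    unless ``clip_to_scale`` is set, in which case values are clipped.
    """
    config = config or SensorConfig()
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"recording file missing columns: {missing}")
    ids = df["calf_id"].astype(str).unique()
    if len(ids) != 1:
        raise IntegrityError(f"recording mixes calf_ids: {sorted(ids)}")
    kwargs = {c: df[c].to_numpy(float) for c in AXIS_CHANNELS}
    if clip_to_scale:
        for c in ("ax", "ay", "az"):
            kwargs[c] = np.clip(kwargs[c], -config.accel_scale, config.accel_scale)
        for c in ("gx", "gy", "gz"):
            kwargs[c] = np.clip(kwargs[c], -config.gyro_scale, config.gyro_scale)
    rec = IMURecording(
        calf_id=str(ids[0]), fs=config.fs, t=df["t"].to_numpy(float), **kwargs
    )
    rec.validate_scales(config)
    return rec


def write_recording(rec: IMURecording, path) -> None:
    """Write a recording to the canonical CSV schema (magnitudes omitted)."""
    df = pd.DataFrame({"t": rec.t, "calf_id": rec.calf_id})
    for c in AXIS_CHANNELS:
        df[c] = getattr(rec, c)
    df.to_csv(path, index=False, float_format="%.6f")


def read_annotations(path, vocabulary: tuple[str, ...] = CORE_VOCABULARY) -> AnnotationTrack:
    """Read an annotation CSV (columns calf_id, behavior, tier, start_s, end_s)."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file missing columns: {missing}")
    ids = df["calf_id"].astype(str).unique()
    if len(ids) != 1:
        raise IntegrityError(f"annotation file mixes calf_ids: {sorted(ids)}")
    intervals = [
        Interval(str(r.behavior), str(r.tier), float(r.start_s), float(r.end_s))
        for r in df.itertuples()
    ]
    return AnnotationTrack(calf_id=str(ids[0]), intervals=intervals, vocabulary=vocabulary)


def write_annotations(track: AnnotationTrack, path) -> None:
    df = pd.DataFrame(
        [
            (track.calf_id, iv.behavior, iv.tier, iv.start_s, iv.end_s)
            for iv in track.intervals
        ],
        columns=list(ANNOTATION_COLUMNS),
    )
    df.to_csv(path, index=False)
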