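"""Synthetic annotated six-axis IMU data for the calf-behavior pipeline.

No public recording of collar IMU data with a calf ethogram exists, so the
generator emulates the signal structure the downstream features are designed
to detect:

* postures (lying, standing) differ in static gravity orientation on the
  accelerometer and in baseline variance,
* natural suckling adds a low-frequency head-nodding oscillation on the
  nodding-axis gyroscope, plus a gravity-aligned acceleration "bob" that
  modulates the acceleration magnitude,
* rumination and feeding add faster chewing oscillations at distinct
  frequencies on a mandibular gyroscope axis,
* coughs are rare, sharp, sub-2 s biphasic transients on the acceleration
  magnitude (plus a gyroscope jerk),
* everything sits on Gaussian per-channel sensor noise.

Signatures are deliberately simple harmonic models — they make the six
behaviors separable by the pipeline's own feature families (orientation,
periodicity, variance, gradients), which is what the generator exists to
exercise; they are not biomechanical claims about calves.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import (
    ALL_CHANNELS,
    AXIS_CHANNELS,
    AnnotationTrack,
    IMURecording,
    Interval,
    SensorConfig,
    attach_magnitudes,
)
from .errors import ScenarioError

_STATE_TOL_S = 1e-6


@dataclass(frozen=True)
class BehaviorSignature:
    """Parametric signal model for one behavior.

    Parameters
    ----------
    behavior_name : str
    base_orientation : tuple or None
        Gravity unit vector on (ax, ay, az); meaningful for state-tier
        behaviors, which define the posture baseline. ``None`` for actions
        and events, which inherit the posture's orientation.
    osc_axis, osc_freq_hz, osc_amp :
        Periodic component: target channel (one of ax..gz), frequency in Hz
        and amplitude in channel units (g or deg/s).
    accel_bob_amp : float
        Amplitude (g) of a same-frequency oscillation along the current
        gravity direction; this is what lifts the acceleration magnitude
        above baseline during vigorous head movement.
    noise_sd_accel, noise_sd_gyro : float
        White-noise SD per accelerometer (g) / gyroscope (deg/s) channel.
        For states this is the baseline floor; for actions it is added on
        top of the posture baseline during the bout.
    transient : (duration_s, peak_amp) or None
        Biphasic acceleration pulse for event behaviors.
    """

    behavior_name: str
    base_orientation: tuple[float, float, float] | None = None
    osc_axis: str | None = None
    osc_freq_hz: float = 0.0
    osc_amp: float = 0.0
    accel_bob_amp: float = 0.0
    noise_sd_accel: float = 0.0
    noise_sd_gyro: float = 0.0
    transient: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd_accel < 0 or self.noise_sd_gyro < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.osc_axis is not None:
            if self.osc_axis not in AXIS_CHANNELS:
                raise ValueError(f"osc_axis must be one of {AXIS_CHANNELS}")
            if self.osc_freq_hz <= 0:
                raise ValueError("oscillation requires a positive frequency")
        if self.base_orientation is not None:
            norm = float(np.linalg.norm(self.base_orientation))
            if abs(norm - 1.0) > 1e-6:
                raise ValueError("base_orientation must be a unit vector")


@dataclass(frozen=True)
class SignatureLibrary:
    """Map behavior name -> signature; all six core behaviors required."""

    signatures: dict[str, BehaviorSignature]

    REQUIRED = (
        "natural_suckling",
        "feeding",
        "rumination",
        "lying",
        "standing",
        "coughing",
    )

    def __post_init__(self) -> None:
        missing = [b for b in self.REQUIRED if b not in self.signatures]
        if missing:
            raise ValueError(f"signature library missing behaviors: {missing}")

    def __getitem__(self, name: str) -> BehaviorSignature:
        return self.signatures[name]

    def to_yaml(self, path) -> None:
        payload = {
            name: {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(sig).items()
                if k != "behavior_name" and v not in (None, 0.0)
            }
            for name, sig in self.signatures.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SignatureLibrary":
        raw = yaml.safe_load(open(path)) or {}
        sigs = {}
        for name, kwargs in raw.items():
            for key in ("base_orientation", "transient"):
                if kwargs.get(key) is not None:
                    kwargs[key] = tuple(kwargs[key])
            sigs[name] = BehaviorSignature(behavior_name=name, **kwargs)
        return cls(sigs)


def default_library() -> SignatureLibrary:
    """Documented default signatures (see docs/methods.md for rationale)."""
    s3 = float(np.sqrt(1 - 0.28**2))
    return SignatureLibrary(
        {
            "lying": BehaviorSignature(
                "lying",
                base_orientation=(s3, 0.0, 0.28),
                noise_sd_accel=0.010,
                noise_sd_gyro=0.8,
            ),
            "standing": BehaviorSignature(
                "standing",
                base_orientation=(0.0, 0.0, 1.0),
                noise_sd_accel=0.030,
                noise_sd_gyro=2.5,
            ),
            "natural_suckling": BehaviorSignature(
                "natural_suckling",
                osc_axis="gy",
                osc_freq_hz=1.5,
                osc_amp=55.0,
                accel_bob_amp=0.30,
                noise_sd_accel=0.04,
                noise_sd_gyro=5.0,
            ),
            "rumination": BehaviorSignature(
                "rumination",
                osc_axis="gx",
                osc_freq_hz=1.1,
                osc_amp=28.0,
                accel_bob_amp=0.06,
                noise_sd_accel=0.015,
                noise_sd_gyro=2.0,
            ),
            "feeding": BehaviorSignature(
                "feeding",
                osc_axis="gx",
                osc_freq_hz=2.4,
                osc_amp=35.0,
                accel_bob_amp=0.30,
                noise_sd_accel=0.035,
                noise_sd_gyro=4.0,
            ),
            "coughing": BehaviorSignature(
                "coughing",
                transient=(0.5, 2.0),
                noise_sd_gyro=0.0,
            ),
        }
    )


@dataclass(frozen=True)
class Scenario:
    """One calf-recording's behavior schedule.

    The state tier must tile [0, duration_s] without gaps; action bouts may
    not overlap each other; event intervals are the cough times.
    """

    calf_id: str
    duration_s: float
    bouts: tuple[Interval, ...]
    seed: int

    def tier(self, tier: str) -> list[Interval]:
        return [iv for iv in self.bouts if iv.tier == tier]

    def validate(self) -> None:
        states = sorted(self.tier("state"), key=lambda iv: iv.start_s)
        if not states:
            raise ScenarioError("state tier must cover the full recording")
        if abs(states[0].start_s) > _STATE_TOL_S or abs(
            states[-1].end_s - self.duration_s
        ) > _STATE_TOL_S:
            raise ScenarioError("state tier must span [0, duration_s]")
        for a, b in zip(states, states[1:]):
            if abs(b.start_s - a.end_s) > _STATE_TOL_S:
                raise ScenarioError(
                    f"state-tier gap between {a.end_s} and {b.start_s}"
                )
        actions = sorted(self.tier("action"), key=lambda iv: iv.start_s)
        for a, b in zip(actions, actions[1:]):
            if b.start_s < a.end_s:
                raise ScenarioError(f"overlapping action bouts: {a} / {b}")


def _bout_slice(iv: Interval, fs: float, n: int) -> slice:
    lo = max(0, int(np.ceil(iv.start_s * fs - 1e-9)))
    hi = min(n, int(np.ceil(iv.end_s * fs - 1e-9)))
    return slice(lo, hi)


def simulate_recording(
    scenario: Scenario,
    library: SignatureLibrary | None = None,
    config: SensorConfig | None = None,
) -> tuple[IMURecording, AnnotationTrack]:
    """Render a scenario into a recording plus its mirroring annotations.

    Deterministic given ``scenario.seed``; the annotation track is the
    schedule itself, so labels are exact by construction.
    """
    library = library or default_library()
    config = config or SensorConfig()
    scenario.validate()
    fs = config.fs
    n = int(round(scenario.duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(scenario.seed)

    accel = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    gravity = np.zeros((n, 3))  # per-sample posture orientation

    for iv in sorted(scenario.tier("state"), key=lambda x: x.start_s):
        sig = library[iv.behavior]
        if sig.base_orientation is None:
            raise ScenarioError(f"state signature {iv.behavior!r} lacks orientation")
        sl = _bout_slice(iv, fs, n)
        m = sl.stop - sl.start
        gravity[sl] = sig.base_orientation
        accel[sl] = sig.base_orientation
        accel[sl] += rng.normal(0.0, sig.noise_sd_accel, (m, 3))
        gyro[sl] += rng.normal(0.0, sig.noise_sd_gyro, (m, 3))

    for iv in sorted(scenario.tier("action"), key=lambda x: x.start_s):
        sig = library[iv.behavior]
        sl = _bout_slice(iv, fs, n)
        m = sl.stop - sl.start
        if m == 0:
            continue
        if sig.osc_axis is not None:
            if sig.osc_freq_hz >= fs / 2:
                raise ScenarioError(
                    f"{iv.behavior}: osc_freq {sig.osc_freq_hz} Hz >= Nyquist"
                )
            phase = rng.uniform(0.0, 2 * np.pi)
            wave = np.sin(2 * np.pi * sig.osc_freq_hz * t[sl] + phase)
            idx = AXIS_CHANNELS.index(sig.osc_axis)
            if idx < 3:
                accel[sl, idx] += sig.osc_amp * wave
            else:
                gyro[sl, idx - 3] += sig.osc_amp * wave
            if sig.accel_bob_amp:
                accel[sl] += gravity[sl] * (sig.accel_bob_amp * wave)[:, None]
        accel[sl] += rng.normal(0.0, sig.noise_sd_accel, (m, 3))
        gyro[sl] += rng.normal(0.0, sig.noise_sd_gyro, (m, 3))

    nod_idx = AXIS_CHANNELS.index(config.nodding_channel) - 3
    for iv in sorted(scenario.tier("event"), key=lambda x: x.start_s):
        sig = library[iv.behavior]
        if sig.transient is None:
            raise ScenarioError(f"event signature {iv.behavior!r} lacks a transient")
        _, peak_amp = sig.transient
        sl = _bout_slice(iv, fs, n)
        m = sl.stop - sl.start
        if m < 3:
            continue
        u = np.linspace(0.0, 1.0, m)
        pulse = np.sin(2 * np.pi * u) * np.hanning(m)  # biphasic, zero-mean-ish
        accel[sl] += gravity[sl] * (peak_amp * pulse)[:, None]
        gyro[sl, nod_idx] += 60.0 * peak_amp * pulse

    np.clip(accel, -config.accel_scale, config.accel_scale, out=accel)
    np.clip(gyro, -config.gyro_scale, config.gyro_scale, out=gyro)
    rec = IMURecording(
        calf_id=scenario.calf_id,
        fs=fs,
        t=t,
        ax=accel[:, 0],
        ay=accel[:, 1],
        az=accel[:, 2],
        gx=gyro[:, 0],
        gy=gyro[:, 1],
        gz=gyro[:, 2],
    )
    track = AnnotationTrack(scenario.calf_id, intervals=list(scenario.bouts))
    return attach_magnitudes(rec), track


# ---------------------------------------------------------------------------
# Schedule generation

#: Lognormal bout-duration parameters (median seconds, sigma of log).
STATE_BOUT_MEDIAN_S = {"lying": 540.0, "standing": 360.0}
ACTION_BOUT_MEDIAN_S = {"natural_suckling": 240.0, "feeding": 180.0, "rumination": 300.0}
BOUT_LOG_SIGMA = 0.45
ACTION_GAP_MEDIAN_S = 90.0
DEFAULT_COUGH_RATE_PER_HOUR = 10.0


def random_scenario(calf_id: str, duration_s: float, seed: int) -> Scenario:
    """Draw a random bout schedule: alternating postures tiling the day and
    action bouts separated by untagged gaps (the "others" time)."""
    rng = np.random.default_rng(seed)
    bouts: list[Interval] = []

    state = str(rng.choice(["lying", "standing"]))
    pos = 0.0
    while pos < duration_s - _STATE_TOL_S:
        dur = rng.lognormal(np.log(STATE_BOUT_MEDIAN_S[state]), BOUT_LOG_SIGMA)
        end = min(pos + dur, duration_s)
        bouts.append(Interval(state, "state", pos, end))
        pos = end
        state = "standing" if state == "lying" else "lying"

    pos = float(rng.lognormal(np.log(ACTION_GAP_MEDIAN_S), BOUT_LOG_SIGMA))
    while pos < duration_s - 30.0:
        behavior = str(rng.choice(list(ACTION_BOUT_MEDIAN_S)))
        dur = rng.lognormal(np.log(ACTION_BOUT_MEDIAN_S[behavior]), BOUT_LOG_SIGMA)
        end = min(pos + dur, duration_s)
        bouts.append(Interval(behavior, "action", pos, end))
        pos = end + rng.lognormal(np.log(ACTION_GAP_MEDIAN_S), BOUT_LOG_SIGMA)

    return Scenario(calf_id, duration_s, tuple(bouts), seed=int(rng.integers(2**31)))


def inject_coughs(scenario: Scenario, rate_per_hour: float, seed: int) -> Scenario:
    """Add Poisson-process cough events (< 2 s each, non-overlapping).

    Events falling too close to the recording ends or to an already-placed
    cough are re-drawn so the seeded Poisson count is preserved.
    """
    if rate_per_hour < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(rate_per_hour * scenario.duration_s / 3600.0)
    placed: list[tuple[float, float]] = []
    margin = 2.0
    for _ in range(n_events):
        for _attempt in range(200):
            start = rng.uniform(margin, scenario.duration_s - margin)
            dur = rng.uniform(0.4, 1.2)
            if all(start + dur + 1.0 < s or start > e + 1.0 for s, e in placed):
                placed.append((start, start + dur))
                break
    events = tuple(
        Interval("coughing", "event", s, e) for s, e in sorted(placed)
    )
    return dataclasses.replace(scenario, bouts=scenario.bouts + events)


def simulate_cohort(
    n_calves: int,
    day_length_s: float,
    seed: int,
    library: SignatureLibrary | None = None,
    config: SensorConfig | None = None,
    cough_rate_per_hour: float = DEFAULT_COUGH_RATE_PER_HOUR,
) -> list[tuple[IMURecording, AnnotationTrack]]:
    """Simulate an annotated cohort of independent calves.

    Each calf gets its own randomized schedule and noise stream, derived
    from one master seed, so the cohort is reproducible end to end.
    """
    if n_calves < 2:
        raise ValueError("a cohort needs at least 2 calves")
    children = np.random.SeedSequence(seed).spawn(n_calves)
    out = []
    for i, child in enumerate(children):
        sub = int(child.generate_state(1)[0] % 2**31)
        scenario = random_scenario(f"calf{i + 1:03d}", day_length_s, sub)
        scenario = inject_coughs(scenario, cough_rate_per_hour, seed=sub + 1)
        out.append(simulate_recording(scenario, library, config))
    return out
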