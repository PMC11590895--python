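import numpy as np
import pytest

from calfsense import pipeline
from calfsense.core import (
    AnnotationTrack,
    IMURecording,
    Interval,
    SensorConfig,
    attach_magnitudes,
)


@pytest.fixture
def config() -> SensorConfig:
    return SensorConfig()


def make_recording(
    n: int = 500,
    fs: float = 25.0,
    calf_id: str = "c1",
    seed: int = 0,
    scale: float = 0.1,
) -> IMURecording:
    """Small noisy recording with gravity on az, magnitudes attached."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    data = rng.normal(0, scale, (n, 6))
    data[:, 2] += 1.0
    rec = IMURecording(calf_id, fs, t, *[data[:, i] for i in range(6)])
    return attach_magnitudes(rec)


def make_track(calf_id: str = "c1", duration: float = 20.0) -> AnnotationTrack:
    return AnnotationTrack(
        calf_id,
        intervals=[Interval("standing", "state", 0.0, duration)],
    )


@pytest.fixture
def recording() -> IMURecording:
    return make_recording()


@pytest.fixture(scope="session")
def cohort_report() -> dict:
    """Full pipeline on the default 48-calf cohort at reduced bout scale.

    Shared across tests: simulating and training three models takes tens
    of seconds, and the report is deterministic for a fixed seed.
    """
    cfg = pipeline.RunConfig(n_calves=48, day_length_s=900.0, n_test=6, seed=1)
    return pipeline.run_all(cfg)
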