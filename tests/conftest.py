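import numpy as np
import pytest

from fallsig import FallSpec, SensorMeta, SensorRecording, SimulationConfig, simulate_recording
from fallsig.timebase import CalendarDateTime


@pytest.fixture
def standing_recording():
    """60 s of quiet upright standing at 100 Hz (acc only)."""
    cfg = SimulationConfig(
        duration_s=60.0, seed=42, sample_rate=100.0, channels=(),
        schedule=[("standing", 60.0)],
    )
    rec, _ = simulate_recording(cfg)
    return rec


@pytest.fixture
def fall_recording():
    """10 min at 100 Hz with one backward fall at 300 s, recovery at +120 s."""
    cfg = SimulationConfig(
        duration_s=600.0, seed=7, sample_rate=100.0, channels=(),
        falls=[FallSpec(time_s=300.0, recovery_s=120.0)],
    )
    return simulate_recording(cfg)


def constant_recording(vector, n=3000, fs=100.0, frame="uniform", start=None):
    """Recording with a constant acceleration vector (plus nothing else)."""
    acc = np.tile(np.asarray(vector, dtype=float), (n, 1))
    meta = SensorMeta(device_type="test", sample_rate=fs)
    start = start or CalendarDateTime(2014, 3, 9, 12, 0, 0)
    return SensorRecording(start, acc, meta, frame=frame)
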