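import numpy as np
import pytest

from cokurt.simulate import simulate_cohort
from cokurt.stream import VitalsSeries


@pytest.fixture(scope="session")
def small_cohort():
    """8 users, 3 sick, 14 days — shared across detector/evaluation tests."""
    return simulate_cohort(8, 3 / 8, days=14, seed=42)


@pytest.fixture
def flat_series():
    """Constant-heart-rate, zero-step 3-hour series at minute cadence."""
    n = 180
    ts = np.datetime64("2024-01-01T00:00:00", "s") + np.arange(n) * np.timedelta64(60, "s")
    return VitalsSeries(
        user_id="flat",
        timestamps=ts,
        heart_rate=np.full(n, 65.0),
        steps=np.zeros(n, dtype=int),
    )


def make_series(heart_rate, steps, cadence=60, user_id="t"):
    n = len(heart_rate)
    ts = np.datetime64("2024-01-01T00:00:00", "s") + np.arange(n) * np.timedelta64(
        cadence, "s"
    )
    return VitalsSeries(
        user_id=user_id,
        timestamps=ts,
        heart_rate=np.asarray(heart_rate, dtype=float),
        steps=np.asarray(steps, dtype=int),
        cadence=cadence,
    )
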