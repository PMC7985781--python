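import numpy as np
import pytest

from uexpand import DetectionSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def make_schedule(rng):
    """Factory for random detection schedules around a random base time."""

    def factory(N: int, t0: float | None = None, spread: float = 0.3) -> DetectionSchedule:
        if t0 is None:
            t0 = float(rng.uniform(-0.5, 0.5))
        times = t0 - rng.uniform(0.0, spread, size=N)
        return DetectionSchedule(t0, tuple(float(t) for t in times))

    return factory
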