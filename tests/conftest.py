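import numpy as np
import pandas as pd
import pytest

from wearagree import CycleAnnotation, SimulationConfig, TimeSeriesRecording


@pytest.fixture
def make_config():
    """Factory for a fast simulation config (short cycles, full protocol)."""

    def _make(**overrides):
        base = dict(
            seed=11,
            n_participants=3,
            cycle_duration_mean_s=2.5,
            cycle_duration_sd_s=0.2,
            rest_s=0.5,
        )
        base.update(overrides)
        return SimulationConfig(**base)

    return _make


@pytest.fixture
def annotation_5x10():
    """Deterministic 5-cycle timeline: 10 s cycles, 5 s rests, starts at 0."""
    return CycleAnnotation(cycles=[(15.0 * i, 15.0 * i + 10.0) for i in range(5)])


@pytest.fixture
def noise_recording():
    """2.95 s of seeded white noise on one channel at 1000 Hz."""
    rng = np.random.default_rng(42)
    n = 2950
    return TimeSeriesRecording(
        times=np.arange(n) / 1000.0,
        data=pd.DataFrame({"acc_x": rng.normal(0.0, 1.0, n)}),
        rate_hz=1000.0,
    )
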