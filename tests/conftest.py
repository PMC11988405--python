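import numpy as np
import pytest

from synsites import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_event_table(amplitudes, duration=1.0, condition="x"):
    """Event table with evenly spaced times, for enumeration-style tests."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    n = len(amplitudes)
    times = (np.arange(n) + 0.5) * duration / max(n, 1)
    return sd.EventTable(
        amplitude=amplitudes,
        time=times,
        condition=condition,
        censored=np.zeros(n, dtype=bool),
        duration=duration,
    )
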