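import numpy as np
import pytest
from hypothesis import settings

import harlearn as hl

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_recording():
    """60 s benchmark-style recording: 6 channels, 3 activity classes + NULL."""
    return hl.generate_recording(hl.benchmark_spec(seed=7, total_duration=60.0))


@pytest.fixture
def small_frames(small_recording):
    return hl.sliding_window_segment(small_recording, T=32, stride=16)
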