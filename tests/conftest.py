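import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def raven_table_text():
    """A minimal well-formed Raven selection table (3 elements, shuffled order)."""
    return (
        "Selection\tView\tChannel\tBegin Time (s)\tEnd Time (s)\tLow Freq (Hz)\tHigh Freq (Hz)\n"
        "2\tSpectrogram 1\t1\t2.780000\t2.980000\t100.000000\t500.000000\n"
        "1\tSpectrogram 1\t1\t0.000000\t0.200000\t100.000000\t500.000000\n"
        "3\tSpectrogram 1\t1\t5.560000\t5.760000\t100.000000\t500.000000\n"
    )
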