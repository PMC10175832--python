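import numpy as np
import pytest

from gammasurge.core import Recording
from gammasurge.synth import default_session_spec, gen_session


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_session():
    """The reference synthetic session (baseline / surge / directed stage)."""
    rec, stages, truth = gen_session(default_session_spec(seed=1))
    return rec, stages, truth


@pytest.fixture()
def short_recording(rng):
    """A 10-s, 3-EEG-channel + ECG recording of plain noise at 256 Hz."""
    fs = 256.0
    sig = rng.standard_normal((4, int(10 * fs))) * 20.0
    return Recording(sig, fs, ["C3", "C4", "O1", "ECG"])
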