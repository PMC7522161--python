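import numpy as np
import pytest

from endostress.signals import EventMarks
from endostress.synth import SessionSpec, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_spec():
    """Three disjoint 60 s windows in a 186 s session at 512 Hz."""
    return SessionSpec(duration_s=186.0, fs=512.0,
                       anchors=EventMarks(2.0, 182.0, cecum=92.0))


@pytest.fixture(scope="session")
def short_session(short_spec):
    """One clean simulated session, shared across read-only tests."""
    return generate_session(short_spec, np.random.default_rng(777))
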