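"""Shared fixtures: small, fast synthetic study conditions.

Simulations in the suite run at a 1 kHz LFP rate (2 kHz ENG) with
recordings of minutes rather than the hour-long 10 kHz originals, which
exercises the identical code paths at tractable size.
"""

import numpy as np
import pytest

from seizlfp.core import Recording
from seizlfp.synth import preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_anaesthetized():
    """Anaesthetized preset scaled to 1 kHz / 30 min for test speed."""
    return preset(
        "anaesthetized_100uM",
        fs_lfp=1000.0,
        fs_eng=2000.0,
        duration_s=1800.0,
        application_time_s=300.0,
        seed=1,
    )


@pytest.fixture
def fast_control():
    return preset("control", fs_lfp=1000.0, duration_s=600.0, seed=1)


def make_recording(samples, fs=1000.0, **kw) -> Recording:
    return Recording(samples=np.asarray(samples, dtype=float), fs=fs, **kw)
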