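import numpy as np
import pytest

from aliflow import synth
from aliflow.ephys import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """Small but structurally complete recording spec for fast tests."""
    return synth.RecordingSpec(
        n_electrodes=4, fs=2000.0, duration_s=30.0, n_active=2, noise_sd=5.0, seed=11
    )


def make_recording(data: np.ndarray, fs: float = 1000.0, **kwargs) -> Recording:
    return Recording(data=np.asarray(data, dtype=float), fs=fs, **kwargs)
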