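import numpy as np
import pytest

from eegsm import (ArtifactSettings, Recording, default_montage,
                   simulate_recording)


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def short_recording(montage, rng):
    """4 s of uncorrelated noise-like data with labels, 128 Hz."""
    data = rng.standard_normal((16, 512)) * 15.0
    return Recording(data, 128.0, montage, pair_id=3, role="leader", system="BSC")


@pytest.fixture()
def clean_simulated(montage):
    """60 s simulated recording, identity correlation, no artifacts."""
    return simulate_recording(np.eye(16), 60.0, 128.0,
                              ArtifactSettings(0.0, 0.0), seed=77)
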