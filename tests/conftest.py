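import numpy as np
import pytest

from gammassr import (
    BackgroundModel,
    EvokedModel,
    StimulusProtocol,
    generate_session,
)

SILENT_BG = BackgroundModel(pink_scale=0.0, gamma_band_power_scale=0.0, artifact_rate=0.0)


@pytest.fixture(scope="session")
def small_session():
    """A 20-stimulus single-channel session with moderate noise, reused across tests."""
    protocol = StimulusProtocol(n_stimuli=20)
    rec, ev = generate_session(
        protocol,
        EvokedModel(),
        BackgroundModel(pink_scale=15.0, gamma_band_power_scale=4.0, artifact_rate=0.0),
        seed=42,
        channels=("global_cortex",),
    )
    return protocol, rec, ev


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
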