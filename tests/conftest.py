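import numpy as np
import pytest

from lfpkit.io_formats import AnimalChannels, SessionConfig


@pytest.fixture
def config():
    """Default 8-channel, 4-animal session config (platform constants)."""
    return SessionConfig(
        num_channels=8,
        animals=[
            AnimalChannels(animal_id=f"m{i}", left_channel=2 * i, right_channel=2 * i + 1)
            for i in range(4)
        ],
    )


@pytest.fixture
def small_config():
    """2-channel config with a tiny packet size for hand-built files."""
    return SessionConfig(
        num_channels=2,
        animals=[AnimalChannels(animal_id="m0", left_channel=0, right_channel=1)],
        samples_per_packet=4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
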