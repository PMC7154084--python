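import numpy as np
import pytest

from megdecode import synth


@pytest.fixture(scope="session")
def small_config():
    """8 channels, 5 classes, 4 trials/class: fast but structurally complete."""
    return synth.SynthConfig(
        n_channels=8, n_trials_per_class=4, n_classes=5, seed=42,
        stage_snr={"pre": 0.0, "perception": 0.5, "preparation": 0.8,
                   "production": 1.2},
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synth.generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
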