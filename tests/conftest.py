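import numpy as np
import pytest

import birdnmf as b


@pytest.fixture(scope="session")
def small_dataset():
    """4 species x 6 recordings x 1.2 s — enough syllables to train on."""
    return b.make_dataset(n_species=4, n_per_species=6, duration=1.2, seed=101)


@pytest.fixture(scope="session")
def small_recordings(small_dataset):
    return b.prepare_dataset(small_dataset)


@pytest.fixture()
def tone():
    """1 s pure 3 kHz tone at 22.05 kHz."""
    rate = 22050
    t = np.arange(rate) / rate
    return b.AudioSignal(np.sin(2 * np.pi * 3000.0 * t), rate)
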