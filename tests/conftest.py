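import numpy as np
import pytest

from efrpipe import synthdata as sd


@pytest.fixture
def noiseless_epochs():
    """40 identical epochs of the default 5-harmonic stack, no noise."""
    truth = sd.EFRGroundTruth()
    silence = sd.NoiseModel(white_sd=0, pink_sd=0, epoch_gain_jitter=0)
    return truth, sd.generate_epochs(truth, silence, 40, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
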