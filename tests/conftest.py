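import numpy as np
import pytest

import dentomorph as dm


@pytest.fixture(scope="session")
def phantoms64():
    """Noise-free 64x64 phantoms, 4 seeds per stage."""
    return [
        dm.generate_phantom(s, (64, 64), seed=100 * s + i, noise_sd=0.0)
        for s in range(1, 7)
        for i in range(4)
    ]


@pytest.fixture(scope="session")
def train_set32():
    """Small noisy 32x32 phantom set for trainer tests."""
    return [dm.generate_phantom(1 + (i % 6), (32, 32), seed=i) for i in range(64)]


@pytest.fixture(scope="session")
def transition_model(phantoms64):
    return dm.build_transition_model(phantoms64, K=16, B=8, smoothing=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
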