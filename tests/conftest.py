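import numpy as np
import pytest

from ieegssl.synthetic import GeneratorParams, generate_dataset


@pytest.fixture(scope="session")
def params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def small_dataset(params):
    """20 segments per class at desk-scale 512 Hz."""
    return generate_dataset({c: 20 for c in range(4)}, params, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
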