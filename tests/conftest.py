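import numpy as np
import pytest

from lycosense import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A down-scaled study config so image tests stay fast; the acceptance
    suite exercises the full-size defaults."""
    return GeneratorConfig(image_shape=(96, 128), speckle_count=3, seed=7)
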