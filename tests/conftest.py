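import numpy as np
import pytest

from cellmech import IntensityImage


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_image(rng):
    return IntensityImage(rng.uniform(100, 200, (128, 128)), 0.325)
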