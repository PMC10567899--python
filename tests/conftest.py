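import numpy as np
import pytest

from fluoroi.stack_io import FluorescenceStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_stack(rng):
    """A small positive random stack (10 frames, 8x8)."""
    data = rng.uniform(50.0, 150.0, size=(10, 8, 8))
    return FluorescenceStack(data=data, frame_interval=0.5, pixel_size=1.2)
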