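import numpy as np
import pytest

from myrmeco.stitching import RawImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def grey_image(value: int, shape=(40, 60)) -> RawImage:
    return RawImage(np.full(shape + (3,), value, dtype=np.uint8))


@pytest.fixture
def grey():
    return grey_image
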