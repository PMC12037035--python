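import logging

import numpy as np
import pytest

from fluoquant.io_core import ImageScene


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.disable(logging.WARNING)
    yield
    logging.disable(logging.NOTSET)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_channel_scene(rng):
    data = rng.integers(0, 1000, size=(2, 64, 64)).astype(np.uint16)
    return ImageScene(data, ["CD20", "CD70"], pixel_size_um=0.05)
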