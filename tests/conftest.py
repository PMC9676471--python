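import numpy as np
import pytest

from maizetrack.geometry import Box


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_box(rng, max_side: float = 100.0, integer: bool = False) -> Box:
    x, y = rng.uniform(-50, 200, size=2)
    w, h = rng.uniform(1.0, max_side, size=2)
    if integer:
        x, y = np.floor([x, y])
        w, h = np.ceil([w, h])
    return Box(x=float(x), y=float(y), w=float(w), h=float(h))
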