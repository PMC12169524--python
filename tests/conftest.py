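import numpy as np
import pytest

from repdet.postprocess import Detection


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_detections(rng, n, num_categories=3, size=100.0):
    """Uniformly random valid detections inside a size x size canvas."""
    dets = []
    for _ in range(n):
        x1, y1 = rng.uniform(0, size * 0.8, 2)
        w, h = rng.uniform(2, size * 0.4, 2)
        dets.append(
            Detection(
                int(rng.integers(num_categories)),
                float(rng.uniform(0.05, 1.0)),
                (float(x1), float(y1), float(min(x1 + w, size)), float(min(y1 + h, size))),
            )
        )
    return dets


@pytest.fixture
def make_detections(rng):
    return lambda n, nc=3, size=100.0: random_detections(rng, n, nc, size)
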