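import numpy as np
import pytest

from maizedet.labels_io import NormalizedBox


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, class_id: int = 0) -> NormalizedBox:
    w = float(rng.uniform(0.02, 0.3))
    h = float(rng.uniform(0.02, 0.3))
    cx = float(rng.uniform(w / 2, 1 - w / 2))
    cy = float(rng.uniform(h / 2, 1 - h / 2))
    return NormalizedBox(class_id, cx, cy, w, h)


@pytest.fixture
def random_boxes(rng):
    def make(n, class_id=0):
        return [random_box(rng, class_id) for _ in range(n)]
    return make
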