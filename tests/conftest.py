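import numpy as np
import pytest

from leafseg import masks_io, synthetic


def random_label_map(rng, size=16, max_instances=4):
    """Random blocky label map: up to ``max_instances`` rectangles painted in order."""
    labels = np.zeros((size, size), dtype=np.int32)
    n = int(rng.integers(0, max_instances + 1))
    for iid in range(1, n + 1):
        h = int(rng.integers(1, size))
        w = int(rng.integers(1, size))
        r = int(rng.integers(0, size - h + 1))
        c = int(rng.integers(0, size - w + 1))
        labels[r : r + h, c : c + w] = iid
    return labels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    cfg = synthetic.RosetteConfig(size=64, k_min=4, k_max=8, seed=7)
    return synthetic.generate_rosette(cfg)


@pytest.fixture(scope="session")
def scene_samples():
    """Eight (image, annotation) pairs for augmentation/training tests."""
    out = []
    for i in range(8):
        cfg = synthetic.RosetteConfig(size=64, k_min=4, k_max=8, seed=50 + i)
        scene = synthetic.generate_rosette(cfg)
        ann = masks_io.mask_to_polygons(scene.labels)
        out.append((scene.image, ann))
    return out
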