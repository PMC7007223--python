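import numpy as np
import pytest

from granulekit import imaging, synthetic


@pytest.fixture
def partition_scene():
    """A rendered single-channel scene targeting f=0.30, v=0.059."""
    scene = synthetic.scene_for_partition(f=0.30, v=0.059, seed=7)
    image, truth = synthetic.make_image(scene, (256, 256), seed=7)
    return image, truth


@pytest.fixture
def disk_image():
    """Five disjoint bright disks on a flat background, plus their pixel counts."""
    img = np.zeros((80, 80))
    centers = [(10, 10), (10, 60), (40, 35), (65, 12), (65, 60)]
    yy, xx = np.mgrid[0:80, 0:80]
    areas = []
    for r, (cy, cx) in zip((3, 4, 5, 3, 4), centers):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[disk] = 1000.0
        areas.append(int(disk.sum()))
    return img, centers, areas


@pytest.fixture
def count_table():
    table, signal_ids = synthetic.make_count_table(synthetic.CountTruth(seed=11))
    return table, signal_ids
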