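import numpy as np
import pytest

import halocell as hc


@pytest.fixture(scope="session")
def params():
    return hc.default_parameters()


@pytest.fixture(scope="session")
def clean_scene():
    """Zero-noise 2-channel scene with 5 interior cells on 640x640."""
    spec = hc.SceneSpec(
        n_cells=5, image_size=(640, 640), seed=21, noise_sd=0.0
    )
    image, truth = hc.generate_scene(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def segmented_scene(clean_scene, params):
    """The clean scene plus its bright-field segmentation."""
    spec, image, truth = clean_scene
    labels, shapes = hc.segment_cells(image.brightfield, params)
    return spec, image, truth, labels, shapes


def make_cell_with_nucleus(
    shape=(120, 120),
    cell_value=300,
    nucleus_value=1000,
    nucleus_radius=9,
    nucleus_offset=(0, 0),
):
    """One rectangular 'cell' label covering most of the frame, with a
    bright nuclear disk planted in the fluorescent plane."""
    cells = np.zeros(shape, dtype=np.int32)
    cells[10:-10, 10:-10] = 1
    plane = np.zeros(shape, dtype=np.uint16)
    plane[cells == 1] = cell_value
    cy, cx = shape[0] // 2 + nucleus_offset[0], shape[1] // 2 + nucleus_offset[1]
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius ** 2
    plane[disk & (cells == 1)] = nucleus_value
    return plane, cells, disk & (cells == 1)
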