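import numpy as np
import pytest

from trabtex.texture import QuantizedImage


@pytest.fixture
def toy_grid():
    """Small 3-level grid whose texture matrices are hand-enumerable."""
    return np.array([
        [0, 0, 1, 1],
        [0, 2, 2, 2],
        [1, 1, 0, 2],
        [2, 1, 0, 0],
    ])


@pytest.fixture
def toy_qimage(toy_grid):
    return QuantizedImage(toy_grid, levels=3)


@pytest.fixture
def checkerboard():
    return np.indices((8, 8)).sum(axis=0) % 2


@pytest.fixture
def disk_mask():
    yy, xx = np.mgrid[0:120, 0:120]
    return (yy - 60) ** 2 + (xx - 60) ** 2 <= 50 ** 2


@pytest.fixture(scope="session")
def small_dataset():
    """34+18 synthetic images at reduced size, with extracted tables."""
    from dataclasses import replace

    from trabtex import extract_tables, gen_dataset
    from trabtex.synthetic import OVX_PARAMS, SHAM_PARAMS

    images, masks, labels = gen_dataset(
        10, 8,
        sham_params=replace(SHAM_PARAMS, image_size=128),
        ovx_params=replace(OVX_PARAMS, image_size=128),
        seed=7)
    tex_s, tex_w, shp = extract_tables(images, masks)
    return tex_s, tex_w, shp, np.array(labels)
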