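import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from histoscore.schemes import ASHCROFT, INFLAMMATION
from histoscore.synthetic import generate_labelled_folders

TILE_PX = 96  # desk-scale tile size used throughout the suite


@pytest.fixture(scope="session")
def fibrosis_tree(tmp_path_factory):
    """Small labelled fibrosis folder tree: 12 tiles per class at 96 px."""
    root = tmp_path_factory.mktemp("fib_tiles")
    manifest = generate_labelled_folders(root, "fibrosis", 12, seed=42, tile_px=TILE_PX)
    return root, manifest


@pytest.fixture(scope="session")
def inflammation_tree(tmp_path_factory):
    """Small labelled inflammation folder tree: 10 tiles per class at 96 px."""
    root = tmp_path_factory.mktemp("infl_tiles")
    manifest = generate_labelled_folders(
        root, "inflammation", 10, seed=43, tile_px=TILE_PX
    )
    return root, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ashcroft():
    return ASHCROFT


@pytest.fixture(scope="session")
def inflammation():
    return INFLAMMATION
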