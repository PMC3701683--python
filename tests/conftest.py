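import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from bnv.fixtures import (
    make_gradient_volume,
    make_two_hemisphere_surface,
    make_toy_network,
)


@pytest.fixture(scope="session")
def two_hemi_surface():
    return make_two_hemisphere_surface(seed=7)


@pytest.fixture(scope="session")
def merged_surface():
    return make_two_hemisphere_surface(gap_mm=0.0, seed=7)


@pytest.fixture(scope="session")
def toy_network():
    return make_toy_network(n_nodes=12, n_modules=3, density=0.4, seed=7)


@pytest.fixture(scope="session")
def gradient_volume():
    # value(i,j,k) = i + 10j + 100k on a 3x3x3 grid, identity affine
    return make_gradient_volume(shape=(3, 3, 3), pattern="axis_gradient")


@pytest.fixture()
def rng():
    return np.random.default_rng(20130704)
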