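import warnings

import numpy as np
import pytest

from msai import (
    PhantomConfig,
    build_phantom,
    default_scheme,
    make_antipodal_grid,
    uniform_odf,
    watson_odf,
)

Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def dense_grid():
    return make_antipodal_grid(250)


@pytest.fixture(scope="session")
def uniform():
    return uniform_odf()


@pytest.fixture(scope="session")
def delta_parallel():
    """Antipodal-delta ODF along z (the standard field direction)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return watson_odf(Z, np.inf)


@pytest.fixture(scope="session")
def delta_perpendicular():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return watson_odf(X, np.inf)


@pytest.fixture(scope="session")
def scheme3():
    return default_scheme(3)


@pytest.fixture(scope="session")
def small_phantom(scheme3):
    """60-voxel phantom covering all six tissue classes."""
    return build_phantom(PhantomConfig(grid_shape=(6, 5, 2)), scheme3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


def random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
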