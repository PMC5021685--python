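import numpy as np
import pytest

from qconvert.gqi import make_odf_directions
from qconvert.schemes import (
    make_dsi_scheme,
    make_multishell_scheme,
    make_single_shell_scheme,
)


@pytest.fixture(scope="session")
def odf8():
    """Default ODF sampling: 8-fold subdivided icosahedron, 321 directions."""
    return make_odf_directions(8)


@pytest.fixture(scope="session")
def odf2():
    return make_odf_directions(2)


@pytest.fixture(scope="session")
def hardi64():
    return make_single_shell_scheme(64, 3000.0, n_b0=1, seed=7)


@pytest.fixture(scope="session")
def hardi256():
    return make_single_shell_scheme(256, 3000.0, n_b0=1, seed=11)


@pytest.fixture(scope="session")
def multishell():
    """The 30@1500 + 64@3000 two-shell scheme."""
    return make_multishell_scheme([(30, 1500.0), (64, 3000.0)], n_b0=1, seed=12)


@pytest.fixture(scope="session")
def dsi_grid():
    """The 257-gradient half-sphere DSI grid at b_max 4000."""
    return make_dsi_scheme(5.0, 4000.0, half_sphere=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
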