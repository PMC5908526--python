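import numpy as np
import pytest

from spermflow.params import GridSpec, PhysicalParams


@pytest.fixture(scope="session")
def params():
    return PhysicalParams.reference()


@pytest.fixture(scope="session")
def small_film():
    """A small thin-film grid (L = 38.8, L_z = 19.4) for solver tests."""
    return GridSpec.thin_film(n_inplane=128)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
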