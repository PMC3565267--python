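import warnings

import numpy as np
import pytest

from chainpack.core import ChainSystem, EnsembleSpec, SimulationBox
from chainpack.lattices import make_dilute_chains, make_fcc, make_hcp


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    # perfect-lattice fixtures trigger the documented jitter-and-retry path
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="degenerate site configuration")
        yield


@pytest.fixture(scope="session")
def fcc_crystal():
    return make_fcc(3)


@pytest.fixture(scope="session")
def hcp_crystal():
    return make_hcp(4)


@pytest.fixture(scope="session")
def dilute_chains():
    ens = EnsembleSpec("uniform", 12, 0.5)
    return make_dilute_chains(15, ens, 0.05, seed=11)


@pytest.fixture(scope="session")
def random_fluid():
    rng = np.random.default_rng(5)
    n, L = 300, 8.0
    return ChainSystem(
        rng.random((n, 3)) * L, [np.array([i]) for i in range(n)], SimulationBox(L)
    )
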