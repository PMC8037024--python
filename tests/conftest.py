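import numpy as np
import pytest

from emtecm.circuit import CircuitParams
from emtecm.lattice import LatticeSpec, build_lattice
from emtecm.mechanics import ElasticParams


@pytest.fixture(scope="session")
def baseline_params() -> CircuitParams:
    return CircuitParams().baseline()


@pytest.fixture(scope="session")
def coupled_params() -> CircuitParams:
    return CircuitParams()


@pytest.fixture(scope="session")
def small_disordered_net():
    """A small diluted, partially phantom periodic lattice."""
    return build_lattice(LatticeSpec(8, 8, 0.85, 0.5, seed=7))


@pytest.fixture(scope="session")
def elastic() -> ElasticParams:
    return ElasticParams(k=1.0, kappa=1e-4, force_tol=1e-9)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
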