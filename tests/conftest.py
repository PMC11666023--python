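import numpy as np
import pytest

from fluorstat import benchmark
from fluorstat.photophysics import Fluorophore, builtin_fluorophores


@pytest.fixture(scope="session")
def library():
    return builtin_fluorophores()


@pytest.fixture(scope="session")
def ru(library):
    return library["[Ru(bpy)3]Br2"]


@pytest.fixture(scope="session")
def fitc(library):
    return library["FITC"]


@pytest.fixture(scope="session")
def operating_points():
    return benchmark.benchmark_conditions()


@pytest.fixture(scope="session")
def fast_fluorophore():
    """Synthetic microsecond-lifetime fluorophore used where SSA event rates
    must stay manageable."""
    return Fluorophore(
        name="synthetic-fast",
        epsilon=1.0e4,
        quantum_yield=0.9,
        lifetime=1.0e-5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
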