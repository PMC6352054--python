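import numpy as np
import pytest

from betadose import (
    combine_branches,
    load_nuclide_library,
    reference_energy_model,
)


@pytest.fixture(scope="session")
def nuclide_library():
    return load_nuclide_library()


@pytest.fixture(scope="session")
def energy_model():
    """The pooled energy-parameterized phi model (cached per session)."""
    model, fits, means = reference_energy_model()
    return model


@pytest.fixture(scope="session")
def refit_results():
    from betadose import refit_all

    return refit_all()


@pytest.fixture(scope="session")
def mean_energies(nuclide_library):
    return {name: n.mean_energy for name, n in nuclide_library.items()}


@pytest.fixture(scope="session")
def y90_spectrum(nuclide_library):
    return combine_branches(nuclide_library["Y-90"])


@pytest.fixture(scope="session")
def c14_spectrum(nuclide_library):
    return combine_branches(nuclide_library["C-14"])


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
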