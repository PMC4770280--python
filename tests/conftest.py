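import numpy as np
import pytest

from mscpbk import DoseEvent, load_kinetic_params, load_species_physiology


@pytest.fixture(scope="session")
def mouse():
    return load_species_physiology("mouse")


@pytest.fixture(scope="session")
def human():
    return load_species_physiology("human")


@pytest.fixture(scope="session")
def reference_params():
    return load_kinetic_params("reference")


@pytest.fixture(scope="session")
def iv_dose():
    """The mouse experiment's dose: 5e5 cells intravenously at t = 0."""
    return (DoseEvent("intravenous", 5e5, 0.0),)


@pytest.fixture(scope="session")
def grid_24h():
    return np.linspace(0.0, 24.0, 97)
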