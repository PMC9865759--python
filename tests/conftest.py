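import numpy as np
import pytest

from toxscreen.ident import IdentificationSettings
from toxscreen.simulate import SimulationConfig
from toxscreen.speclib import build_fixture_library, make_entry


@pytest.fixture(scope="session")
def fixture_lib():
    return build_fixture_library()


@pytest.fixture(scope="session")
def settings():
    return IdentificationSettings()


@pytest.fixture
def sim_cfg():
    """Short-gradient config covering all fixture retention times (<= 6.42 min)."""
    return SimulationConfig(gradient_length=420.0, seed=1234)


@pytest.fixture(scope="session")
def toy_entry():
    """A fast-eluting synthetic compound for cheap simulator tests."""
    return make_entry(
        "ToyDrug",
        "C10H14N2",
        "+",
        rt_min=0.5,
        ms2_peaks=[(130.0651, 100.0), (117.0573, 40.0), (80.0495, 20.0)],
    )


@pytest.fixture(scope="session")
def toy_entry_b():
    """A second synthetic compound, disjoint fragments, nearby RT."""
    return make_entry(
        "ToyDrugB",
        "C9H13NO2",
        "+",
        rt_min=0.8,
        ms2_peaks=[(135.0441, 100.0), (91.0542, 55.0), (65.0386, 12.0)],
    )
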