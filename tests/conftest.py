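import numpy as np
import pytest

import dabengage as de


@pytest.fixture(scope="session")
def toy_pair():
    """Default synthetic complex pair (81/70/77 Å terminal separations)."""
    return de.make_toy_complex(de.ToyComplexSpec())


@pytest.fixture(scope="session")
def merged_toy(toy_pair):
    vh, vk = toy_pair
    merged, rmsd = de.merge_complexes(vh, vk)
    return merged, rmsd


@pytest.fixture(scope="session")
def dual_dab():
    return de.dual_dab_architecture()


@pytest.fixture(scope="session")
def vegf():
    return de.vegf_antigen()


@pytest.fixture(scope="session")
def calibration():
    return de.MALLSCalibration()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
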