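import pytest

from collagen_ptm.peptides import load_sites
from collagen_ptm.xlink_quant import QuantCalibration


@pytest.fixture(scope="session")
def sites():
    return load_sites()


@pytest.fixture(scope="session")
def site_a1_87(sites):
    return sites[("alpha1(I)", "Lys-87")]


@pytest.fixture(scope="session")
def site_a1_918_930(sites):
    return sites[("alpha1(I)", "Lys-918/930")]


@pytest.fixture(scope="session")
def site_a2_5n(sites):
    return sites[("alpha2(I)", "Lys-5^N")]


@pytest.fixture()
def calibration():
    return QuantCalibration(specific_activity=1.0e9, collagen_mol=1.0e-6)
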