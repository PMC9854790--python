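import numpy as np
import pytest

from eprstab.spin_sim import AcquisitionSettings, SpinSystem, simulate_spectrum
from eprstab.synthetic_data import PBN_ADDUCT_1, PBN_ADDUCT_2, fixtures_table1


@pytest.fixture(scope="session")
def pbn_pair():
    """The two persistent PBN adduct species at their 65:35 weights."""
    return (PBN_ADDUCT_1, PBN_ADDUCT_2)


@pytest.fixture(scope="session")
def default_settings():
    return AcquisitionSettings()


@pytest.fixture(scope="session")
def mixture_spectrum(pbn_pair, default_settings):
    """Noiseless 65:35 two-species mixture on the default 1024-point axis."""
    return simulate_spectrum(list(pbn_pair), default_settings)


@pytest.fixture(scope="session")
def oil_records():
    return fixtures_table1()


@pytest.fixture()
def single_line_system():
    return SpinSystem(label="single", g=2.0057, a_N=14.9, a_H=0.0, weight=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
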