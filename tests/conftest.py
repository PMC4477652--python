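import numpy as np
import pytest

from iminotherm.synthetic_data import (
    DEFAULT_CATALYSIS,
    ExperimentDesign,
    hsp17_preset,
    gen_exchange_series,
)
from iminotherm.thermo_core import BasePairThermo


@pytest.fixture(scope="session")
def catalysis():
    return DEFAULT_CATALYSIS


@pytest.fixture(scope="session")
def g28_truth():
    """Strong CG pair with realistic transfer-state parameters."""
    return BasePairThermo(
        label="G28", dH_diss=193.5, dS_diss=561.9,
        dH_tr_int=55.0, dS_tr_int=25.0, d=1.5,
    )


@pytest.fixture(scope="session")
def noiseless_series():
    """Noise-free exchange-rate surfaces for the wild-type parameter ladder."""
    spec = hsp17_preset(
        "hsp17", seed=11, design=ExperimentDesign(seed=11, rate_noise_frac=0.0)
    )
    return spec, gen_exchange_series(spec)


@pytest.fixture(scope="session")
def noisy_series():
    """5% multiplicative noise on the same design grid."""
    spec = hsp17_preset("hsp17", seed=12)
    return spec, gen_exchange_series(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20150504)
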