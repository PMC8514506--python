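import numpy as np
import pytest

from condense_rheo.presets import ALL_PRESETS, P_H, PK_H, S_L, S_P
from condense_rheo.viscoelastic import BurgersParameters


@pytest.fixture(scope="session")
def presets():
    return ALL_PRESETS


@pytest.fixture
def ph_burgers():
    """P:H-like medium: eta = 0.53 Pa s, tau1 = 125 ms."""
    return P_H.burgers


@pytest.fixture
def pkh_burgers():
    """pK:H-like medium: eta = 0.30 Pa s, tau1 = 45 ms."""
    return PK_H.burgers


@pytest.fixture
def water():
    """Newtonian water at 25 C as a degenerate Burgers medium."""
    return BurgersParameters(8.9e-4, 0.0, 1e-12, 1e-9)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
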