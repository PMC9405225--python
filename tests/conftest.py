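import numpy as np
import pytest

from vwbr import correlation as co
from vwbr import physchem as pc


@pytest.fixture(scope="session")
def props21() -> pc.MediumProperties:
    """Water/oxygen properties at the 21.0 C reference temperature."""
    return pc.medium_properties(21.0)


@pytest.fixture(scope="session")
def experimental_constants() -> co.SherwoodConstants:
    return co.SherwoodConstants(
        k=1.68, alpha=0.551, gamma=1.18, provenance="experimental"
    )


@pytest.fixture(scope="session")
def simulation_constants() -> co.SherwoodConstants:
    return co.SherwoodConstants(
        k=3.85, alpha=0.532, gamma=0.947, provenance="simulation"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
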