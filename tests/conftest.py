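import numpy as np
import pytest

from timingfit import model_fitting as mf


@pytest.fixture(scope="session")
def design() -> mf.SessionDesign:
    """Canonical four-block session design with the default HRF."""
    return mf.SessionDesign()


@pytest.fixture(scope="session")
def coarse_grid() -> mf.GridSpec:
    return mf.GridSpec.coarse()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
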