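import numpy as np
import pytest

from mrtsim.config import default_config
from mrtsim.geometry import CollimatorSpec, design_collimator


@pytest.fixture(scope="session")
def default_coll():
    return CollimatorSpec()


@pytest.fixture(scope="session")
def default_slits(default_coll):
    return design_collimator(default_coll)


@pytest.fixture(scope="session")
def default_spectrum():
    return default_config().spectrum.generate()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def field_report():
    """Shared full-scale simulation + analysis of the default setup.

    3e6 source histories with 4-fold splitting (1.2e7 effective histories),
    detector PSF calibrated to the 20 um central-beam penumbra at 1 mm,
    peaks anchored to 300 mGy/s at 1 mm.
    """
    from mrtsim.analysis import characterize_field

    cfg = default_config(
        **{"transport.histories": 3_000_000, "transport.chunks": 12,
           "transport.seed": 20240901}
    )
    return characterize_field(cfg)
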