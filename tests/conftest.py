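import numpy as np
import pytest

from akinetics import generate_variant_suite


@pytest.fixture(scope="session")
def suite():
    return generate_variant_suite()


@pytest.fixture(scope="session")
def wt(suite):
    return suite["WT"]


@pytest.fixture(scope="session")
def f86w(suite):
    return suite["F86W"]


@pytest.fixture(scope="session")
def coarse_amp_grid():
    """Coarser concentration grid for unit tests where speed matters."""
    return np.geomspace(1.0, 1e4, 21)
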