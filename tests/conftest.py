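import numpy as np
import pytest

from inkflow.nozzleflow import NozzleGeometry, NozzleSegment, default_geometry
from inkflow.rsm import make_bb_design


@pytest.fixture(scope="session")
def bb_design():
    """The standard 17-run, 5-centre Box-Behnken design over the ink cube."""
    return make_bb_design()


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def capillary():
    """A single 0.125 mm x 10 mm cylinder, the Hagen-Poiseuille oracle case."""
    return NozzleGeometry((NozzleSegment(10.0, 0.125, 0.125),))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
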