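import numpy as np
import pytest

import pilax as px

# Printed helical parameters of the two filament forms under study.
WIDE = px.HelicalSymmetry(rise=9.33, twist=92.5)
NARROW = px.HelicalSymmetry(rise=11.26, twist=84.3)


@pytest.fixture(scope="session")
def wide_sym():
    return WIDE


@pytest.fixture(scope="session")
def narrow_sym():
    return NARROW


@pytest.fixture(scope="session")
def toy_subunit():
    subunit, truth = px.make_toy_subunit(seed=1, radial_extent=35.0)
    return subunit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
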