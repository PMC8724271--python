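import numpy as np
import pytest

from pararange.lattice import Box, LatticeSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def cm_spec():
    """Default cardiomyocyte lattice: 120 x 20 x 20 um, axis-aligned."""
    return LatticeSpec()


@pytest.fixture
def cm_box():
    """One cardiomyocyte cuboid centred at the origin."""
    return Box((0.0, 0.0, 0.0), (60.0, 10.0, 10.0))
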