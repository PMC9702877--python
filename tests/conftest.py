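import numpy as np
import pytest
from hypothesis import settings

from fragkin.synthetic.populations import Component, PopulationSpec

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20_220_167)


@pytest.fixture
def mono_only_spec():
    """Population consisting solely of the 167 bp mononucleosome peak."""
    return PopulationSpec(components=(Component("monoN", 1.0, 167, 8),), max_len=1000)


@pytest.fixture
def two_component_spec():
    return PopulationSpec(
        components=(
            Component("monoN", 0.7, 167, 8),
            Component("diN", 0.3, 350, 20),
        ),
        max_len=1000,
    )
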