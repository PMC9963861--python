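import numpy as np
import pytest

import nmrdfit as nf


@pytest.fixture(scope="session")
def default_grid():
    """The 60-point acquisition grid, 10 kHz - 20 MHz."""
    return nf.make_frequency_grid(nf.FrequencyGridSpec())


@pytest.fixture(scope="session")
def qre_grid():
    """Acquisition grid with the dense 1.8-3.3 MHz quadrupole window."""
    return nf.make_frequency_grid(
        nf.FrequencyGridSpec(qre_window=(1.8e6, 3.3e6, 40)))


@pytest.fixture
def rng():
    return np.random.default_rng(20230217)


@pytest.fixture(scope="session")
def residence_preset_20wt():
    """Residence-lifetime 2D model, 20%wt 268 K published row."""
    spec, params, T, sample = nf.get_preset("table4_20wt_268K")
    return spec, params
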