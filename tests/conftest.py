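import numpy as np
import pytest

from flpaint.simkit import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tcspc_config():
    """Acquisition constants only (no targets): 12.5 ns window, 50 ps bins,
    0.25 ns FWHM IRF centred at 0.5 ns."""
    return SimulationConfig(targets=())
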