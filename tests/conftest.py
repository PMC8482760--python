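import numpy as np
import pytest

from nanopulse.physics import Electrolyte, PoreSpec, blockade_amplitude, open_pore_current
from nanopulse.simulate import SimCondition, SimSettings, generate_trace


@pytest.fixture(scope="session")
def settings():
    return SimSettings()


@pytest.fixture(scope="session")
def i0(settings):
    return open_pore_current(settings.pore, settings.electrolyte, 0.3)


@pytest.fixture(scope="session")
def snr4_trace(settings):
    """10 s labeled trace at SNR 4 with a moderate event rate."""
    cond = SimCondition(c_np_nM=0.3, d_np_nm=10.0, duration_ms=1.0, snr=4.0,
                        trace_length_s=10.0)
    return generate_trace(cond, seed=101, settings=settings)


@pytest.fixture(scope="session")
def quiet_trace(settings):
    """Essentially noise-free trace (very high SNR)."""
    cond = SimCondition(c_np_nM=0.1, d_np_nm=12.0, duration_ms=2.0, snr=1e6,
                        trace_length_s=10.0)
    return generate_trace(cond, seed=77, settings=settings)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
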