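import numpy as np
import pytest

from virtuchlor import Instrument, zero_calibrate


@pytest.fixture
def rng():
    return np.random.default_rng(20230501)


@pytest.fixture
def quiet_instrument():
    """A zeroed instrument with the detector read noise switched off."""
    inst = Instrument()
    inst.detector.read_noise_sd = 0.0
    air = zero_calibrate(inst)
    return inst, air


@pytest.fixture
def noisy_instrument():
    """A zeroed instrument with the default read noise."""
    inst = Instrument()
    air = zero_calibrate(inst)
    return inst, air
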