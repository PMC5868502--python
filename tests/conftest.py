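import numpy as np
import pytest

from irtbat.radiometric import DEFAULT_CALIBRATION, TemperatureFrame
from irtbat.roi import ApexSet
from irtbat.synthetic import PhantomSpec


@pytest.fixture
def calibration():
    return DEFAULT_CALIBRATION


@pytest.fixture
def spec():
    return PhantomSpec()


@pytest.fixture
def step_edge_frame():
    """Vertical step edge at column 40: skin 34 °C left, background 22 °C right."""
    temp = np.full((60, 100), 34.0)
    temp[:, 40:] = 22.0
    return TemperatureFrame(temp_c=temp, timestamp=0.0, frame_id="edge")


@pytest.fixture
def edge_apices():
    """Apices straddling rows 10-40 with the right-side lateral edge at x=40."""
    return ApexSet(
        superolateral_left=(5.0, 10.0),
        superolateral_right=(40.0, 10.0),
        acromioclavicular_left=(3.0, 40.0),
        acromioclavicular_right=(40.0, 40.0),
        sternal=(20.0, 45.0),
        frame_shape=(60, 100),
    )
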