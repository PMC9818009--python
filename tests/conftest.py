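import numpy as np
import pytest

from peepwatch import Waveform
from peepwatch.synth import DEFAULT_TEMPLATES, CallType

SR = 51_200.0


@pytest.fixture(scope="session")
def sr():
    return SR


@pytest.fixture(scope="session")
def peep_template():
    return DEFAULT_TEMPLATES[CallType.PEEP]


@pytest.fixture(scope="session")
def alarm_template():
    return DEFAULT_TEMPLATES[CallType.ALARM_CALL]


def sine(freq, duration, amplitude=1.0, rate=SR):
    t = np.arange(int(round(duration * rate))) / rate
    return Waveform(amplitude * np.sin(2 * np.pi * freq * t), rate)


@pytest.fixture(scope="session")
def tone_2khz():
    return sine(2000.0, 1.0)
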