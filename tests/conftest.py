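import numpy as np
import pytest

from rrmswitch.rotamerfit import KarplusTable

# self-consistent test constants; the packaged default file carries the
# documented literature values instead
TEST_KARPLUS = KarplusTable({"NCg": (2.4, 0.3, 0.5), "CpCg": (0.6, 4.0, 0.6)})

# chi1 targets realising the UP / DOWN surface signatures
# (gauche+ = -60 deg, gauche- = +60 deg, trans = 180 deg)
UP_CHI1 = {426: -60.0, 428: -60.0, 429: -60.0,
           455: -60.0, 466: 180.0, 468: 180.0}
DOWN_CHI1 = {426: 180.0, 428: 180.0, 429: -60.0,
             455: 180.0, 466: 60.0, 468: -60.0}
TEMPLATE_RESTYPES = {426: "PHE", 428: "TYR", 429: "HIS",
                     455: "PHE", 466: "PHE", 468: "PHE"}


@pytest.fixture
def karplus():
    return TEST_KARPLUS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
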