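import numpy as np
import pytest

from catchsim.scenario_generator import catch_family


@pytest.fixture(scope="session")
def family():
    """The bundled charge-complementary peptide family."""
    return catch_family()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)
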