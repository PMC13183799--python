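import numpy as np
import pytest

from constancy import scenes as sc


@pytest.fixture(scope="session")
def illuminants():
    return sc.make_illuminant_set()


@pytest.fixture(scope="session")
def neutral(illuminants):
    return illuminants["neutral"]


@pytest.fixture(scope="session")
def competitors_blue(illuminants, neutral):
    return sc.make_competitor_set(sc.DEFAULT_TARGET_REFLECTANCE,
                                  illuminants["blue"], neutral)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
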