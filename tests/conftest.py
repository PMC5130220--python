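import pytest

from bleedcap import (
    DEFAULT_SEVERITY_BANDS,
    DEFAULT_TARGET_AREA,
    DEFAULT_WHITE_BALANCE,
    CapsuleConfig,
)
from bleedcap.reference import REFERENCE_SOLUTIONS


@pytest.fixture(scope="session")
def wb():
    return DEFAULT_WHITE_BALANCE


@pytest.fixture(scope="session")
def area():
    return DEFAULT_TARGET_AREA


@pytest.fixture(scope="session")
def bands():
    return DEFAULT_SEVERITY_BANDS


@pytest.fixture(scope="session")
def capsule_cfg():
    return CapsuleConfig()


@pytest.fixture(scope="session")
def solutions():
    return REFERENCE_SOLUTIONS
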