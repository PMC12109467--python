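import pytest

from hvad_acoustics import load_embedded_cohort
from hvad_acoustics.ml import CVScheme


@pytest.fixture(scope="session")
def cohort():
    clinical, profiles = load_embedded_cohort()
    return clinical, profiles


@pytest.fixture(scope="session")
def profiles(cohort):
    return cohort[1]


@pytest.fixture(scope="session")
def clinical(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def ltocv():
    return CVScheme("ltocv", 11)


@pytest.fixture(scope="session")
def loocv():
    return CVScheme("loocv", 11)
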