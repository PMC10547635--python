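import pytest

from scinject import InjectionProtocol, SubjectCovariates


@pytest.fixture
def male():
    return SubjectCovariates.default_male()


@pytest.fixture
def female():
    return SubjectCovariates.default_female()


@pytest.fixture
def saline_protocol():
    """0.5 mL saline at 6 mL/min through a 6 mm 32G needle."""
    return InjectionProtocol(v_inj=500.0, q_inj=6000.0)
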