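import pytest

from phenodyn.calibrate import growth_rate_from_doubling
from phenodyn.models import ModelParams, PhenotypeState


@pytest.fixture(scope="session")
def r_hour() -> float:
    """Intrinsic growth rate from the 27 h doubling time."""
    return growth_rate_from_doubling(27.0)


@pytest.fixture(scope="session")
def untreated_params(r_hour) -> ModelParams:
    """The untreated best-fit parameter regime."""
    return ModelParams(r=r_hour, alpha=0.484, beta=1.00)


@pytest.fixture
def half_half() -> PhenotypeState:
    return PhenotypeState(0.5, 0.5)
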