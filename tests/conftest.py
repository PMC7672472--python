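import pytest

from exoprofile import fixtures
from exoprofile.models import AptamerSpec, DigestionParams, SamplingSchedule


@pytest.fixture
def ma46() -> AptamerSpec:
    return AptamerSpec(aptamer_id="MA-46", full_length_nt=46, protected_length_nt=41)


@pytest.fixture
def mmc_aptamer() -> AptamerSpec:
    return AptamerSpec(aptamer_id="MMC1", full_length_nt=73, protected_length_nt=42)


@pytest.fixture
def noiseless_params() -> DigestionParams:
    return fixtures.DEFAULT_DIGESTION.model_copy(update={"noise_cv": 0.0})


@pytest.fixture
def schedule() -> SamplingSchedule:
    return fixtures.DEFAULT_SCHEDULE
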