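import pytest

from pcdmi.config import ScoreConfig
from pcdmi.synthetic_cohort import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> ScoreConfig:
    return ScoreConfig()


@pytest.fixture(scope="session")
def cohort66():
    """A seeded 66-patient synthetic cohort with ground truth."""
    return generate_cohort(SimConfig(n_patients=66), seed=20120101)
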