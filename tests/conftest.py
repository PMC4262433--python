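import pytest

from tryplipid import StudyConfig


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    """Default study-emulation configuration (seed 0)."""
    return StudyConfig()


@pytest.fixture(scope="session")
def noise_free(config) -> StudyConfig:
    return config.replace(noise_cv=0.0)
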