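import pytest

from ffrcea import default_config, generate_cohort, load_bundled_config


@pytest.fixture(scope="session")
def korea():
    return load_bundled_config("korea")


@pytest.fixture(scope="session")
def us():
    return load_bundled_config("us")


@pytest.fixture(scope="session")
def uk():
    return load_bundled_config("uk")


@pytest.fixture(scope="session")
def korea_utilities(korea):
    return korea.utilities


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic claims cohort with balanced arms for fast tests."""
    return generate_cohort(default_config(n_patients=4000, p_ffr=0.5, seed=42))
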