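import pytest
from hypothesis import settings

from nbscea import default_background_mortality, load_baseline

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline():
    """The packaged Shenzhen 2018 baseline with the synthetic course library.

    Session-scoped: tests that mutate it must work on ``baseline.copy()``.
    """
    return load_baseline()


@pytest.fixture(scope="session")
def background(baseline):
    return default_background_mortality(baseline.econ.horizon)
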