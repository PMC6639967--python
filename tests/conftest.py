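import pytest
from hypothesis import settings

from uticea import default_parameter_set, default_structure

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    """Bundled reference-case point estimates."""
    return default_parameter_set()


@pytest.fixture(scope="session")
def structure():
    return default_structure()
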