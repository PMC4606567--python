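import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from lipidshot.lipid_model import build_default_registry, default_standards
from lipidshot.simulate import reference_plasma_fixture


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def standards():
    return default_standards()


@pytest.fixture(scope="session")
def plasma_truth():
    """The synthetic plasma-like ground truth (session-cached: construction
    scans the enumerated database for collisions)."""
    return reference_plasma_fixture()
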