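import pytest

from selsites.core import ThresholdConfig
from selsites.fixtures import canonical_spec, write_workspace


@pytest.fixture(scope="session")
def defaults() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture(scope="session")
def demo_spec():
    return canonical_spec(seed=7)


@pytest.fixture(scope="session")
def demo_workspace(demo_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("workspace")
    return write_workspace(demo_spec, out)
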