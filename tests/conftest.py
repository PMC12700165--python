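import pytest

from rumenaux.config import ThresholdConfig
from rumenaux.synthetic import simulate_bundle


@pytest.fixture(scope="session")
def cfg():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle, shared read-only across tests."""
    return simulate_bundle(seed=1)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    from rumenaux.synthetic import write_bundle
    path = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, path)
    return path
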