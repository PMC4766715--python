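import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20160224)


@pytest.fixture(scope="session")
def e2e_fixture_dir(tmp_path_factory):
    """One shared synthetic submission for pipeline-level tests."""
    from metannot.fixtures import generate_fixtures

    d = tmp_path_factory.mktemp("dataset")
    generate_fixtures(d, seed=42)
    return d
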