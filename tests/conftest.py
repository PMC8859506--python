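import numpy as np
import pytest
from hypothesis import settings

from copdce.parameters import write_parameters
from copdce.synthetic import base_case_bundle, toy_two_severity_bundle

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    """Canonical analysis bundle (printed point estimates + synthetic stand-ins)."""
    return base_case_bundle()


@pytest.fixture()
def fresh_bundle():
    return base_case_bundle()


@pytest.fixture(scope="session")
def toy():
    """Hand-traceable two-severity toy bundle."""
    return toy_two_severity_bundle()


@pytest.fixture(scope="session")
def config_path(tmp_path_factory, bundle):
    path = tmp_path_factory.mktemp("cfg") / "base_case.yaml"
    write_parameters(bundle, path)
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
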