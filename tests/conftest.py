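import pytest

from asthma_cea.analyses import run_base_case
from asthma_cea.synthetic import reference_fixture


@pytest.fixture(scope="session")
def fixture_bundle():
    return reference_fixture()


@pytest.fixture(scope="session")
def params(fixture_bundle):
    return fixture_bundle.parameters


@pytest.fixture(scope="session")
def base_case(params):
    """The fixture base case, shared across tests (parameters are copied
    before any perturbation, so session scope is safe)."""
    return run_base_case(params)
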