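import pytest

from cytophylo.reference import make_reference_fixtures


@pytest.fixture(scope="session")
def bundle():
    """The reconstructed published-survey fixture bundle."""
    return make_reference_fixtures()


@pytest.fixture(scope="session")
def arrangements(bundle):
    return bundle.arrangements


@pytest.fixture(scope="session")
def standard(arrangements):
    return arrangements["suzukii_tani_standard"]


@pytest.fixture(scope="session")
def cytoform_d_order(arrangements):
    return arrangements["cytoform_D"]


@pytest.fixture(scope="session")
def profiles(bundle):
    return bundle.profiles


@pytest.fixture(scope="session")
def registry(bundle):
    return bundle.registry
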