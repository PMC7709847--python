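import pytest

from teleroi import fracture_clinic_fixture, run_bundle


@pytest.fixture(scope="session")
def bundle():
    """The bundled three-year fracture-clinic scenario."""
    return fracture_clinic_fixture()


@pytest.fixture(scope="session")
def result(bundle):
    """Full evaluation of the bundled scenario at the default FTA bounds."""
    return run_bundle(bundle)
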