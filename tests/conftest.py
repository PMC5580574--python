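import pytest

from wqassess import qilihai_fixture


@pytest.fixture(scope="session")
def fixture_bundle():
    """(monitoring table, standards, weights) for the published dataset."""
    return qilihai_fixture()


@pytest.fixture(scope="session")
def standards(fixture_bundle):
    return fixture_bundle[1]


@pytest.fixture(scope="session")
def weights(fixture_bundle):
    return fixture_bundle[2]


@pytest.fixture(scope="session")
def fitted():
    """Fitted assessment of the published dataset (shared; results are frozen)."""
    from wqassess import WaterQualityAssessment

    return WaterQualityAssessment.qilihai().fit()
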