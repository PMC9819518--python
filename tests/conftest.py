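import pytest

from hisbench import bundled_fixture, evaluate_city, weights_for_framework


@pytest.fixture(scope="session")
def bundle():
    return bundled_fixture("khon_kaen_2019")


@pytest.fixture(scope="session")
def printed_weights(bundle):
    """Group weights rounded to the two decimals the benchmark tables carry."""
    return weights_for_framework(bundle.framework, bundle.pcms, decimals=2)


@pytest.fixture(scope="session")
def evaluation(bundle, printed_weights):
    return evaluate_city(bundle.framework, bundle.observation, printed_weights)
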