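import pytest

from minigem.synth import SyntheticScenario, make_toy_model


@pytest.fixture(scope="session")
def chain_model():
    """8-gene chain toy model plus its by-construction essential set."""
    model, truth = make_toy_model(8, "chain", seed=0)
    return model, truth


@pytest.fixture()
def scenario():
    return SyntheticScenario(seed=7)
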