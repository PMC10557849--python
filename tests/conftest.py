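import pytest

from isoatlas.simulate import make_demo_scenario


@pytest.fixture(scope="session")
def scenario():
    """The packaged six-isoform scenario with known tier/frequency truth."""
    return make_demo_scenario(seed=1)


@pytest.fixture(scope="session")
def locus(scenario):
    return scenario["locus"]


@pytest.fixture(scope="session")
def atlas(scenario):
    return scenario["atlas"]
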