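import pytest

from thermonet import fixtures


@pytest.fixture(scope="session")
def yeast_conditions():
    return fixtures.yeast_conditions()


@pytest.fixture(scope="session")
def glycolysis_energies():
    return fixtures.glycolysis_energies()


@pytest.fixture(scope="session")
def glycolysis_dg0():
    return fixtures.glycolysis_dg0()


@pytest.fixture(scope="session")
def glycolysis_reactions():
    return fixtures.glycolysis_reactions()
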