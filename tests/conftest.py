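import numpy as np
import pandas as pd
import pytest

from routemerit import fixtures, gen_fixture_bundle


@pytest.fixture(scope="session")
def table7():
    return fixtures.load_table7()


@pytest.fixture(scope="session")
def table9():
    return fixtures.load_table9()


@pytest.fixture(scope="session")
def metabolite_fit():
    """Calibrated metabolite merit model (model 1), shared across tests."""
    return fixtures.metabolite_merit_model().fit()


@pytest.fixture(scope="session")
def route_fit():
    """Calibrated route merit model (model 2)."""
    return fixtures.route_merit_model().fit()


@pytest.fixture(scope="session")
def bundle():
    return gen_fixture_bundle(seed=11)
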