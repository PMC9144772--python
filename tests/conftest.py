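import numpy as np
import pytest

import extractopt as eo


@pytest.fixture(scope="session")
def factors():
    return eo.load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return eo.load_fixture("table2")


@pytest.fixture(scope="session")
def table4():
    return eo.load_fixture("table4")


@pytest.fixture(scope="session")
def table5():
    return eo.load_fixture("table5")


@pytest.fixture(scope="session")
def weights():
    return eo.WeightScheme(weights={"DISS": 0.75, "PolyIII": 0.25})


@pytest.fixture(scope="session")
def averaged_table2(table2):
    return eo.aggregate_replicates(table2)


@pytest.fixture(scope="session")
def refit_model(table2):
    return eo.fit_quadratic(table2, "composite")


@pytest.fixture(scope="session")
def anova(refit_model, table2):
    return eo.anova_quadratic(refit_model, table2, "composite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
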