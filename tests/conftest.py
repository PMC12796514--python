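import numpy as np
import pytest

from koalapop.demography import build_leslie
from koalapop.landscape import SyntheticLandscape
from koalapop.synthetic import make_covariates, make_rate_table, reference_schedule


@pytest.fixture(scope="session")
def landscape():
    """A fixed, well-identified 30x30 km study landscape.

    Two disc parks; the hotspot at the centre cell of the first; one road
    running exactly along a row of cell centres (y = 5.5) plus a diagonal.
    """
    return SyntheticLandscape.from_geometry(
        extent=(30.0, 30.0),
        parks=[(10.5, 10.5, 4.0), (22.5, 20.5, 3.0)],
        roads=[((0.0, 5.5), (30.0, 5.5)), ((2.0, 0.0), (28.0, 30.0))],
        hotspot=(10.5, 10.5),
    )


@pytest.fixture(scope="session")
def covariates(landscape):
    return make_covariates(landscape, seed=3)


@pytest.fixture(scope="session")
def rate_table():
    return make_rate_table(n_studies=4, missing_fraction=0.0, seed=1)


@pytest.fixture(scope="session")
def reference_leslie():
    surv, fert = reference_schedule()
    return build_leslie(fert, surv)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
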