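import numpy as np
import pytest

import polymax as pm

# families with finite variance used across optimization / property tests;
# pareto and power need a shape, fixed at the values exercised throughout
OPT_FAMILY_SPECS = {
    "normal": ("normal",),
    "uniform": ("uniform",),
    "exponential": ("exponential", 1.0),
    "pareto": ("pareto", 4.0),
    "logistic": ("logistic",),
    "power": ("power", 2.0),
}


@pytest.fixture(scope="session")
def models():
    return {name: pm.make_distribution(*spec) for name, spec in OPT_FAMILY_SPECS.items()}


@pytest.fixture(scope="session")
def cis_optima(models):
    """maximize_cis results for every (family, k) pair used by property tests."""
    out = {}
    for name, model in models.items():
        for k in range(2, 11):
            out[(name, k)] = pm.maximize_cis(model, k)
    return out


@pytest.fixture(scope="session")
def opt_optima(models):
    out = {}
    for name, model in models.items():
        for k in range(2, 11):
            out[(name, k)] = pm.maximize_opt(model, k)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
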