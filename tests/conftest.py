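import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import paninvasion as pv

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario():
    """A mid-size scenario with the default study conditions."""
    return pv.generate_scenario(pv.ScenarioConfig(n_regions=150, seed=11))


@pytest.fixture(scope="session")
def potentials_table(scenario):
    return pv.potentials_from_scenario(scenario)


@pytest.fixture()
def small_stack():
    """Four smooth standardized covariates on a 30x30 grid."""
    return pv.generate_covariate_stack((30, 30), 4, smoothness=1.0, seed=3)


@pytest.fixture()
def gradient_stack():
    """Single west-east linear gradient covariate, 20x20."""
    vals = np.tile(np.linspace(-2, 2, 20), (20, 1))
    return pv.CovariateStack(["grad"], [pv.Grid(vals, (0.0, 10.0), 0.5)])


def make_regions(region_ids, invaded=(), level="country"):
    return pd.DataFrame(
        {
            "region": list(region_ids),
            "level": level,
            "invaded": [r in set(invaded) for r in region_ids],
        }
    )
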