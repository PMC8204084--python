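import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import glucoflux as gf
from glucoflux.estimation import adipose_submodel_simulator
from glucoflux.whole_body import TabulatedSignal

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> gf.ParameterSet:
    """Packaged final-model parameterization."""
    return gf.ParameterSet()


@pytest.fixture(scope="session")
def meal_forcings(params):
    """The packaged 6-h parametric meal."""
    return gf.default_meal_forcings(params)


@pytest.fixture(scope="session")
def meal_traj(params, meal_forcings):
    """One shared 6-h meal simulation at default tolerances."""
    return gf.simulate(params, meal_forcings)


@pytest.fixture(scope="session")
def gt_signal(meal_traj):
    """Interstitial glucose from the meal simulation as a fixed input."""
    return TabulatedSignal(meal_traj.times, meal_traj.column("Gt"), "Gt")


@pytest.fixture(scope="session")
def adipose_sim(params, gt_signal, meal_forcings):
    """Fast adipose sub-model simulator used by the fitting tests."""
    return adipose_submodel_simulator(
        params, gt_signal, meal_forcings,
        t_grid=np.arange(0.0, 361.0, 5.0), rtol=1e-5, atol=1e-8)
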