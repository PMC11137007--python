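import numpy as np
import pytest

from leafopt import (
    RateFunction,
    RateSet,
    SeasonParams,
    SolverSettings,
    get_scenario,
    solve,
)

# test-grid resolution: coarse enough to keep the suite fast, fine enough
# for the tolerances asserted here
N_TEST = 4000


@pytest.fixture(scope="session")
def fig2_rates() -> RateSet:
    return get_scenario("fig2").rates


@pytest.fixture(scope="session")
def fig2_params() -> SeasonParams:
    return SeasonParams(T=1.0, L0=1.0, s_max=0.132, n_steps=N_TEST)


@pytest.fixture(scope="session")
def settings() -> SolverSettings:
    return SolverSettings(n_steps=N_TEST)


@pytest.fixture(scope="session")
def fig2_traj(fig2_rates, fig2_params, settings):
    return solve(fig2_rates, fig2_params, settings)


@pytest.fixture(scope="session")
def fig4_b4_scenario():
    return get_scenario("fig4", b1=4.0, n_steps=N_TEST)


@pytest.fixture(scope="session")
def fig4_b4_traj(fig4_b4_scenario, settings):
    sc = fig4_b4_scenario
    return solve(sc.rates, sc.params, settings)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240529)
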