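import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from scaffoldwave import (
    NondimParameters,
    SolverSettings,
    make_ic_cosh,
    make_ic_quadratic,
    solve_moving_boundary,
)


@pytest.fixture(scope="session")
def q_growth():
    """Standard growth parameters: kappa = 0.3, s = 0.2, mu = eta = 1."""
    return NondimParameters(kappa=0.3, s=0.2)


@pytest.fixture(scope="session")
def q_decay():
    return NondimParameters(kappa=-0.3, s=0.2)


@pytest.fixture(scope="session")
def ic_quadratic():
    return make_ic_quadratic(omega=0.03, L0=1.0, s=0.2)


@pytest.fixture(scope="session")
def ic_cosh():
    return make_ic_cosh(A0=0.05, B0=0.01)


@pytest.fixture(scope="session")
def traj_growth(q_growth, ic_quadratic):
    """kappa = 0.3 run to t = 50 on the test grid (travelling-wave regime)."""
    st = SolverSettings(n_grid=101, t_end=50.0)
    return solve_moving_boundary(q_growth, ic_quadratic, st)


@pytest.fixture(scope="session")
def traj_decay(q_decay, ic_quadratic):
    """kappa = -0.3 run to t = 50 (stationary regime)."""
    st = SolverSettings(n_grid=101, t_end=50.0)
    return solve_moving_boundary(q_decay, ic_quadratic, st)
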