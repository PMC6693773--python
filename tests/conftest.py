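import numpy as np
import pytest

from ventmech.cohort import load_cohort
from ventmech.constitutive import MaterialParams
from ventmech.fem import SolverConfig
from ventmech.geometry import assign_fibers, make_idealized_ventricle


@pytest.fixture(scope="session")
def cohort():
    return load_cohort()


@pytest.fixture(scope="session")
def coarse_ventricle():
    """Small chamber + mesh, cheap enough for repeated FE solves."""
    stack, mesh = make_idealized_ventricle(
        long_axis_len=40.0, endo_radius=22.0, wall_thickness=5.0,
        n_slices=6, n_circ=12, n_layers=2)
    fibers = assign_fibers(mesh)
    return stack, mesh, fibers


@pytest.fixture(scope="session")
def soft_params():
    return MaterialParams()  # c1=1, D1=0.5, K1=1 kPa, frozen exponents


@pytest.fixture(scope="session")
def fast_solver():
    return SolverConfig(load_steps=4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
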