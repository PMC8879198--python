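import numpy as np
import pytest

from emfit import fixtures as fx
from emfit.density import DensitySimParams, simulate_density


@pytest.fixture(scope="session")
def helix30():
    return fx.make_structure(fx.FixtureSpec("helix", 30))

@pytest.fixture(scope="session")
def bundle60():
    return fx.make_structure(fx.FixtureSpec("three-helix-bundle", 60))

@pytest.fixture(scope="session")
def dimer40():
    return fx.make_structure(fx.FixtureSpec("c2-dimer", 40))

@pytest.fixture(scope="session")
def hinge40():
    return fx.make_structure(fx.FixtureSpec("two-domain-hinge", 40))


@pytest.fixture(scope="session")
def hinge_fit_problem(hinge40):
    """Reference two-domain model, its sigma=6 map, and a 25-degree bent
    start pose -- the standard flexible-fitting recovery task."""
    bent = fx.perturb(hinge40, {"type": "hinge", "angle_deg": 25}, seed=11)
    params = DensitySimParams(sigma=6.0, voxel_size=3.0)
    exp_map = simulate_density(hinge40, "auto", params)
    return hinge40, bent, exp_map


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
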