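import numpy as np
import pytest

from beadscape import MagnetizationGrid, build_scenario, run_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_grid(rng, shape=(2, 5, 6), cell=(2e-7, 2e-7, 1e-7), scale=1e5):
    """Random magnetization grid (all cells active)."""
    M = rng.normal(size=shape + (3,)) * scale
    return MagnetizationGrid(
        M=M, cell_size=cell, origin=(0.0, 0.0, -cell[2] * shape[0] + cell[2] / 2)
    )


@pytest.fixture
def small_grid(rng):
    return random_grid(rng)


# -- scenario runs (shared, expensive) ----------------------------------


@pytest.fixture(scope="session")
def disc_result():
    return run_scenario(build_scenario("disc", coarse=True))


@pytest.fixture(scope="session")
def triangle_result():
    return run_scenario(build_scenario("triangles", coarse=True))


@pytest.fixture(scope="session")
def stripe_result():
    return run_scenario(build_scenario("stripes", coarse=True))


@pytest.fixture(scope="session")
def oval_result():
    return run_scenario(build_scenario("ovals", coarse=True))
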