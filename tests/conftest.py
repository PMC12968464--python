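import numpy as np
import pytest

from densnav import design, observer, simbold, stimulus


@pytest.fixture(scope="session")
def scale():
    return stimulus.make_density_scale(2, 196, 26)


@pytest.fixture(scope="session")
def session(scale):
    """One fully simulated run (yoked, with behaviour) on a fixed seed."""
    rng = np.random.default_rng(1234)
    pairs = design.make_pair_set(scale, rng)
    run = design.build_run(pairs, scale, rng)
    return observer.simulate_session(run, scale, rng=rng)


@pytest.fixture(scope="session")
def small_grid():
    """A small grid with four disjoint ROIs for imaging tests."""
    return simbold.make_grid_and_rois(shape=(14, 14, 10))
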