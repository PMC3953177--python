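import numpy as np
import pytest

import evodecoy as ed


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Compile the numba kernels once up front so individual test timings
    reflect steady-state behavior."""
    conf = ed.extended_conformation("ACDEF")
    ed.AMWEnergy().score(conf)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sequence():
    return "ACDEFGHIKL"


def random_conformation(sequence, rng):
    angles = rng.uniform(-179.0, 180.0, (len(sequence), 3))
    return ed.Conformation(sequence=sequence, angles=angles)


@pytest.fixture
def toy_system():
    return ed.make_toy_system(8, entries_per_window=3, seed=7)


@pytest.fixture
def toy_energy(toy_system):
    return ed.ToyEnergy(toy_system.target.angles,
                        counter=ed.BudgetCounter())
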