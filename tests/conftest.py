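import numpy as np
import pytest

import bgsens as bg


@pytest.fixture(scope="session")
def abc():
    """Open chain A<->B<->C: K=1, kappa=(1,9), chemostats A (x=2) and C (x=1)."""
    return bg.fixture("abc_chain")


@pytest.fixture(scope="session")
def abc_closed():
    return bg.fixture("abc_closed")


@pytest.fixture(scope="session")
def enzyme():
    return bg.fixture("enzyme_module")


@pytest.fixture(scope="session")
def abc_steady(abc):
    return bg.steady_state(abc)


@pytest.fixture(scope="session")
def abc_sens(abc):
    return bg.augment(abc)


@pytest.fixture(scope="session")
def abc_lin(abc_sens, abc_steady):
    return bg.linearize(abc_sens, abc_steady)


@pytest.fixture(scope="session")
def abc_lin_f1(abc_sens, abc_steady):
    """Linearization observing only the flow through r1."""
    return bg.linearize(abc_sens, abc_steady, outputs=["r1"])


def random_chain(rng: np.random.Generator, n_species: int) -> bg.ReactionNetwork:
    """Closed linear chain with random positive K and kappa."""
    species = [
        bg.SpeciesSpec(f"S{i}", K=float(rng.uniform(0.2, 5.0)),
                       x_init=float(rng.uniform(0.2, 3.0)))
        for i in range(n_species)
    ]
    reactions = [
        bg.ReactionSpec(f"r{i}", kappa=float(rng.uniform(0.2, 5.0)),
                        forward={f"S{i}": 1}, reverse={f"S{i+1}": 1})
        for i in range(n_species - 1)
    ]
    return bg.build_network(species, reactions)
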