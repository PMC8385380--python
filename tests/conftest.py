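import numpy as np
import pytest

import repdyn as rd


@pytest.fixture
def rainy():
    return rd.make_fixture("table3_rainy")


@pytest.fixture
def drought():
    return rd.make_fixture("table3_drought")


@pytest.fixture
def coord_game():
    return rd.make_fixture("coord_2x2")


@pytest.fixture
def space_2x2():
    return rd.GenotypeSpace((2, 2))


@pytest.fixture
def hetero():
    return rd.make_fixture("hetero_advantage")


def random_distribution(space, rng):
    return rd.GenotypeDistribution(space, rng.dirichlet(np.ones(space.size)))


def random_profile(space, rng):
    return rd.AllelicProfile(
        space, tuple(rng.dirichlet(np.ones(k)) for k in space.alleles_per_locus)
    )
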