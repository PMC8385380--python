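"""Built-in worked examples and seeded random instance generators.

The named fixtures are the small worked objects every treatment of these
dynamics leans on:

``table3_rainy`` / ``table3_drought``
    two 2-locus × 3-allele fitness matrices, each with a single pure Nash
    equilibrium — at alleles ``(0, 2)`` (rainy) and ``(2, 0)`` (drought);
``coord_2x2``
    the symphony/beach coordination game (payoffs 2 / 1 / 0);
``periodic_exp``
    a two-genotype periodic environment alternating fitness ``e^{1/2}``
    and ``e^{1/3}`` in antiphase with period 200 — the canonical example
    of an environment with no convergent genotype;
``hetero_advantage``
    the 2-allele diploid heterozygote-advantage matrix [[0,1],[1,0]],
    whose stable equilibrium is the polymorphic state (1/2, 1/2).
"""

from __future__ import annotations

import math

import numpy as np

from .environments import EnvironmentProcess
from .genotype_core import DiploidLandscape, FitnessLandscape, GenotypeSpace
from .potential_games import PotentialGame, game_from_landscape

__all__ = ["FIXTURE_NAMES", "make_fixture", "random_landscape"]

FIXTURE_NAMES = (
    "table3_rainy",
    "table3_drought",
    "coord_2x2",
    "periodic_exp",
    "hetero_advantage",
)

_RAINY = [0.40, 0.60, 0.80,
          0.48, 0.55, 0.75,
          0.20, 0.51, 0.70]

_DROUGHT = [0.40, 0.48, 0.20,
            0.60, 0.55, 0.51,
            0.80, 0.75, 0.70]


def make_fixture(name: str):
    """Return a named fixture (landscape, game or environment)."""
    if name == "table3_rainy":
        return FitnessLandscape(GenotypeSpace((3, 3)), np.asarray(_RAINY), label="rainy")
    if name == "table3_drought":
        return FitnessLandscape(GenotypeSpace((3, 3)), np.asarray(_DROUGHT), label="drought")
    if name == "coord_2x2":
        w = FitnessLandscape(
            GenotypeSpace((2, 2)), np.asarray([2.0, 0.0, 0.0, 1.0]), label="coordination"
        )
        return game_from_landscape(w)
    if name == "periodic_exp":
        space = GenotypeSpace((2,))
        strong_g = FitnessLandscape(
            space, np.asarray([math.exp(0.5), math.exp(1.0 / 3.0)]), label="phase_g"
        )
        strong_h = FitnessLandscape(
            space, np.asarray([math.exp(1.0 / 3.0), math.exp(0.5)]), label="phase_h"
        )
        # generation t (1-based): landscape 0 while t <= 100 mod 200, else 1
        schedule = [0] * 100 + [1] * 100
        return EnvironmentProcess.from_schedule((strong_g, strong_h), schedule)
    if name == "hetero_advantage":
        return DiploidLandscape(np.asarray([[0.0, 1.0], [1.0, 0.0]]), label="hetero_advantage")
    raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")


def random_landscape(
    space: GenotypeSpace,
    distribution: str = "uniform",
    seed: int = 0,
    *,
    lognormal_sigma: float = 1.0,
) -> FitnessLandscape:
    """A seeded random fitness landscape with strictly positive values.

    ``uniform`` draws from (0, 1]; ``lognormal`` from a log-normal with the
    given sigma.  Exact ties between genotype fitnesses (which would make
    the landscape non-generic) are broken by redrawing.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        if distribution == "uniform":
            vals = 1.0 - rng.random(space.size)  # (0, 1]
        elif distribution == "lognormal":
            vals = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=space.size)
        else:
            raise ValueError(f"unknown distribution {distribution!r}")
        if np.unique(vals).size == space.size:
            return FitnessLandscape(space, vals, label=f"random-{distribution}-{seed}")
    raise RuntimeError("could not draw a generic landscape")  # pragma: no cover
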