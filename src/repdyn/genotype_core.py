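"""Genotype and allele state spaces, distributions, and fitness aggregation.

The population-genetic models implemented in this package all live on one of
two state spaces:

* the simplex ``Δ(Γ)`` of distributions over the finite genotype set ``Γ``
  (a genotype is a tuple of allele indices, one per locus), or
* the polytope ``Θ = Δ_1 × … × Δ_m`` of per-locus allelic frequency
  vectors, which is the natural state space when loci segregate
  independently (linkage equilibrium).

This module provides the containers for both, the projection ``ρ`` from
genotype distributions to allelic profiles (marginalisation), its right
inverse ``ρ⁻¹`` (the linkage-equilibrium product lift), and the fitness
aggregates — population mean fitness and per-allele marginal fitness — that
drive every replicator-type update.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import reduce
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SIMPLEX_TOL",
    "DimensionError",
    "UndefinedMarginalError",
    "ExtinctionError",
    "GenotypeSpace",
    "FitnessLandscape",
    "GenotypeDistribution",
    "AllelicProfile",
    "DiploidLandscape",
    "GameteState",
    "mean_fitness",
    "marginal_fitness",
    "marginal_fitness_vector",
    "project_rho",
    "lift_rho_inverse",
    "linkage_deviation",
]

#: tolerance on probability-mass conservation enforced after every operation
SIMPLEX_TOL = 1e-12


class DimensionError(ValueError):
    """Operands are defined over mismatched spaces."""


class UndefinedMarginalError(ValueError):
    """Marginal fitness requested for an allele with zero marginal probability."""


class ExtinctionError(RuntimeError):
    """Population mean fitness is zero; the replicator update is undefined."""


def _as_simplex(vec, *, name: str) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if v.ndim != 1:
        raise DimensionError(f"{name} must be a 1-d vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(v < -SIMPLEX_TOL):
        raise ValueError(f"{name} has negative entries")
    v = np.clip(v, 0.0, None)
    total = v.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} sums to {total!r}, not 1")
    return v / total


@dataclass(frozen=True)
class GenotypeSpace:
    """The set Γ of genotypes over ``m`` loci.

    A genotype is a tuple of 0-based allele indices, one per locus.
    Genotypes are enumerated in row-major order over the loci, giving a
    bijection with ``0 .. size-1``.
    """

    alleles_per_locus: tuple[int, ...]

    def __post_init__(self) -> None:
        alleles = tuple(int(k) for k in self.alleles_per_locus)
        if len(alleles) < 1:
            raise ValueError("a genotype space needs at least one locus")
        if any(k < 1 for k in alleles):
            raise ValueError("every locus needs at least one allele")
        object.__setattr__(self, "alleles_per_locus", alleles)

    @property
    def num_loci(self) -> int:
        return len(self.alleles_per_locus)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.alleles_per_locus

    @property
    def size(self) -> int:
        return int(np.prod(self.alleles_per_locus))

    def index(self, genotype: Sequence[int]) -> int:
        """Row-major flat index of a genotype (tuple of allele indices)."""
        return int(np.ravel_multi_index(tuple(genotype), self.shape))

    def genotype(self, index: int) -> tuple[int, ...]:
        """Inverse of :meth:`index`."""
        return tuple(int(i) for i in np.unravel_index(index, self.shape))

    def genotypes(self) -> Iterator[tuple[int, ...]]:
        return itertools.product(*(range(k) for k in self.alleles_per_locus))


@dataclass
class FitnessLandscape:
    """A fitness value ``w_g ≥ 0`` per genotype, optionally tagged by environment.

    Values above 1 are deliberately allowed: the dynamics only ever use
    fitness ratios, and time-varying examples naturally use values like
    ``e^{1/2}``.
    """

    space: GenotypeSpace
    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != self.space.size:
            raise DimensionError(
                f"landscape has {v.size} values for {self.space.size} genotypes"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("fitness values must be finite")
        if np.any(v < 0):
            raise ValueError("fitness values must be non-negative")
        if not np.any(v > 0):
            raise ValueError("at least one genotype must have positive fitness")
        self.values = v

    @property
    def tensor(self) -> np.ndarray:
        """Fitness values reshaped to one axis per locus."""
        return self.values.reshape(self.space.shape)


@dataclass
class GenotypeDistribution:
    """A point ``d`` of the genotype simplex Δ(Γ)."""

    space: GenotypeSpace
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = _as_simplex(self.weights, name="genotype weights")
        if w.size != self.space.size:
            raise DimensionError(
                f"distribution has {w.size} weights for {self.space.size} genotypes"
            )
        self.weights = w

    @classmethod
    def uniform(cls, space: GenotypeSpace) -> "GenotypeDistribution":
        return cls(space, np.full(space.size, 1.0 / space.size))

    @classmethod
    def point_mass(cls, space: GenotypeSpace, genotype: Sequence[int]) -> "GenotypeDistribution":
        w = np.zeros(space.size)
        w[space.index(genotype)] = 1.0
        return cls(space, w)

    @property
    def tensor(self) -> np.ndarray:
        return self.weights.reshape(self.space.shape)

    def support(self) -> np.ndarray:
        return np.flatnonzero(self.weights > 0)


@dataclass
class AllelicProfile:
    """A point ``q = (q_1, …, q_m)`` of Θ: one frequency vector per locus."""

    space: GenotypeSpace
    freqs: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.freqs) != self.space.num_loci:
            raise DimensionError(
                f"profile has {len(self.freqs)} loci for a {self.space.num_loci}-locus space"
            )
        cleaned = []
        for i, (q, k) in enumerate(zip(self.freqs, self.space.alleles_per_locus)):
            q = _as_simplex(q, name=f"locus-{i} frequencies")
            if q.size != k:
                raise DimensionError(
                    f"locus {i} has {q.size} frequencies for {k} alleles"
                )
            cleaned.append(q)
        self.freqs = tuple(cleaned)

    @classmethod
    def uniform(cls, space: GenotypeSpace) -> "AllelicProfile":
        return cls(space, tuple(np.full(k, 1.0 / k) for k in space.alleles_per_locus))

    @classmethod
    def point_mass(cls, space: GenotypeSpace, genotype: Sequence[int]) -> "AllelicProfile":
        freqs = []
        for k, a in zip(space.alleles_per_locus, genotype):
            q = np.zeros(k)
            q[a] = 1.0
            freqs.append(q)
        return cls(space, tuple(freqs))

    def stacked(self) -> np.ndarray:
        """All per-locus vectors concatenated (for distances/serialisation)."""
        return np.concatenate(self.freqs)


@dataclass
class DiploidLandscape:
    """Symmetric fitness matrix ``W_ij`` over unordered allele pairs.

    Single-locus diploid genotypes are unordered pairs (no position
    effects); symmetry is enforced on construction by averaging.
    """

    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.values, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise DimensionError(f"diploid fitness must be square, got {W.shape}")
        if not np.all(np.isfinite(W)):
            raise ValueError("diploid fitness values must be finite")
        if np.any(W < 0):
            raise ValueError("diploid fitness values must be non-negative")
        self.values = 0.5 * (W + W.T)

    @property
    def num_alleles(self) -> int:
        return self.values.shape[0]


@dataclass
class GameteState:
    """Two-locus diploid state: gamete frequencies plus pair fitnesses.

    The gamete space is a two-locus :class:`GenotypeSpace`; ``pair_fitness``
    is a symmetric matrix over gametes giving the fitness of the diploid
    genotype formed by each (unordered) gamete pair.
    """

    space: GenotypeSpace
    frequencies: np.ndarray
    pair_fitness: DiploidLandscape

    def __post_init__(self) -> None:
        if self.space.num_loci != 2:
            raise DimensionError("GameteState requires a two-locus gamete space")
        self.frequencies = _as_simplex(self.frequencies, name="gamete frequencies")
        if self.frequencies.size != self.space.size:
            raise DimensionError("gamete frequency vector does not match the space")
        if self.pair_fitness.num_alleles != self.space.size:
            raise DimensionError("pair fitness matrix does not match the gamete count")

    def distribution(self) -> GenotypeDistribution:
        return GenotypeDistribution(self.space, self.frequencies)


# ---------------------------------------------------------------------------
# fitness aggregation


def _check_space(a, b) -> None:
    if a.space != b.space:
        raise DimensionError("operands are defined over different genotype spaces")


def mean_fitness(d: GenotypeDistribution, w: FitnessLandscape) -> float:
    """Population mean fitness ``w̄ = Σ_g d_g w_g``."""
    _check_space(d, w)
    return float(d.weights @ w.values)


def marginal_fitness(
    d: GenotypeDistribution, w: FitnessLandscape, locus: int, allele: int
) -> float:
    """Mean fitness of genotypes carrying ``allele`` at ``locus``, weighted by d.

    This is the conditional expectation ``E[w_g | g_locus = allele]`` under
    the current distribution.  Undefined (raises) when the allele has zero
    marginal probability.
    """
    _check_space(d, w)
    num, den = _marginal_num_den(d.tensor, w.tensor, locus)
    if den[allele] <= 0.0:
        raise UndefinedMarginalError(
            f"allele {allele} at locus {locus} has zero marginal probability"
        )
    return float(num[allele] / den[allele])


def _marginal_num_den(d_tensor: np.ndarray, w_tensor: np.ndarray, locus: int):
    """Vectors ``Σ_{g∈C_aj} w_g d_g`` and ``Σ_{g∈C_aj} d_g`` over alleles j."""
    axes = tuple(ax for ax in range(d_tensor.ndim) if ax != locus)
    num = (d_tensor * w_tensor).sum(axis=axes)
    den = d_tensor.sum(axis=axes)
    return num, den


def marginal_fitness_vector(
    d: GenotypeDistribution, w: FitnessLandscape, locus: int
) -> np.ndarray:
    """Marginal fitness of every allele at ``locus`` (NaN where undefined)."""
    _check_space(d, w)
    num, den = _marginal_num_den(d.tensor, w.tensor, locus)
    out = np.full_like(num, np.nan)
    pos = den > 0
    out[pos] = num[pos] / den[pos]
    return out


# ---------------------------------------------------------------------------
# ρ and ρ⁻¹


def project_rho(d: GenotypeDistribution) -> AllelicProfile:
    """Marginalise a genotype distribution to per-locus allele frequencies."""
    t = d.tensor
    m = d.space.num_loci
    freqs = []
    for i in range(m):
        axes = tuple(ax for ax in range(m) if ax != i)
        q = t.sum(axis=axes) if axes else t.copy()
        freqs.append(q / q.sum())
    return AllelicProfile(d.space, tuple(freqs))


def lift_rho_inverse(q: AllelicProfile) -> GenotypeDistribution:
    """Linkage-equilibrium lift: ``d_g = Π_i q_{i, g_i}`` (product measure)."""
    tensor = reduce(np.multiply.outer, q.freqs)
    w = tensor.ravel()
    return GenotypeDistribution(q.space, w / w.sum())


def linkage_deviation(d: GenotypeDistribution) -> float:
    """Max-norm distance of ``d`` from its linkage-equilibrium product lift.

    Zero exactly when the population is in linkage equilibrium; single-locus
    spaces are trivially always at zero.
    """
    le = lift_rho_inverse(project_rho(d))
    return float(np.max(np.abs(d.weights - le.weights)))
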