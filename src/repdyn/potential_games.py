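"""Finite games, potential functions and pure Nash enumeration.

A fixed multi-locus fitness landscape induces an *identical-interests game*
between the loci: each locus is a player, its alleles are the player's pure
actions, and every player receives the common payoff ``w_g`` at the action
profile spelling genotype ``g``.  The population mean fitness is then the
multilinear (mixed) extension of the common payoff and acts as the game's
potential, so the pure Nash equilibria are exactly the local maxima of the
fitness landscape under single-locus allele swaps.

Beyond that special case, the module verifies and constructs exact
potentials for arbitrary finite games by path integration of unilateral
payoff differences, and supplies the best-reply and ε-Nash utilities used
by the convergence diagnostics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_core import DimensionError, FitnessLandscape, _as_simplex

__all__ = [
    "FiniteGame",
    "PotentialGame",
    "as_mixed_profile",
    "game_from_landscape",
    "potential_value",
    "expected_payoff",
    "unilateral_payoffs",
    "enumerate_pure_nash",
    "find_potential",
    "best_reply_step",
    "epsilon_nash_gap",
]

POTENTIAL_TOL = 1e-9


@dataclass
class FiniteGame:
    """A finite strategic-form game.

    ``payoffs[i]`` is player *i*'s payoff tensor, with one axis per player
    (so ``payoffs[i][a_1, …, a_n]`` is *i*'s payoff at that pure profile).
    """

    payoffs: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        tensors = tuple(np.asarray(p, dtype=float) for p in self.payoffs)
        if not tensors:
            raise ValueError("a game needs at least one player")
        shape = tensors[0].shape
        if len(shape) != len(tensors):
            raise DimensionError(
                f"{len(tensors)} players but payoff tensors have {len(shape)} axes"
            )
        for i, t in enumerate(tensors):
            if t.shape != shape:
                raise DimensionError(f"player {i} payoff tensor has shape {t.shape} != {shape}")
            if not np.all(np.isfinite(t)):
                raise ValueError(f"player {i} payoffs contain non-finite values")
        self.payoffs = tensors

    @property
    def num_players(self) -> int:
        return len(self.payoffs)

    @property
    def action_counts(self) -> tuple[int, ...]:
        return self.payoffs[0].shape

    def profiles(self):
        return itertools.product(*(range(k) for k in self.action_counts))


@dataclass
class PotentialGame:
    """A finite game together with an exact potential Φ.

    The defining property — every unilateral payoff difference equals the
    corresponding potential difference — is verified on construction.
    """

    game: FiniteGame
    potential: np.ndarray

    def __post_init__(self) -> None:
        phi = np.asarray(self.potential, dtype=float)
        if phi.shape != self.game.action_counts:
            raise DimensionError("potential tensor shape does not match the game")
        err = _potential_defect(self.game, phi)
        if err > POTENTIAL_TOL:
            raise ValueError(
                f"potential property violated: max unilateral defect {err:.3e}"
            )
        self.potential = phi

    @property
    def num_players(self) -> int:
        return self.game.num_players

    @property
    def action_counts(self) -> tuple[int, ...]:
        return self.game.action_counts


def _potential_defect(game: FiniteGame, phi: np.ndarray) -> float:
    """Max over players and unilateral edges of |ΔΦ − Δu_i|."""
    worst = 0.0
    for i, u in enumerate(game.payoffs):
        # differences along player i's axis must match for u_i and phi
        du = np.diff(u, axis=i)
        dphi = np.diff(phi, axis=i)
        if du.size:
            worst = max(worst, float(np.max(np.abs(du - dphi))))
    return worst


def as_mixed_profile(game: FiniteGame | PotentialGame, x: Sequence) -> tuple[np.ndarray, ...]:
    """Validate a per-player tuple of probability vectors against the game."""
    counts = game.action_counts
    if len(x) != len(counts):
        raise DimensionError(f"profile has {len(x)} players for a {len(counts)}-player game")
    out = []
    for i, (xi, k) in enumerate(zip(x, counts)):
        xi = _as_simplex(xi, name=f"player-{i} strategy")
        if xi.size != k:
            raise DimensionError(f"player {i} strategy has {xi.size} entries for {k} actions")
        out.append(xi)
    return tuple(out)


def game_from_landscape(w: FitnessLandscape) -> PotentialGame:
    """The loci-as-players identical-interests game of a fitness landscape.

    Player *i*'s actions are locus *i*'s alleles; every player's payoff at a
    pure profile is the fitness of the genotype it spells, and the common
    payoff is itself the potential.
    """
    tensor = w.tensor
    game = FiniteGame(tuple(tensor for _ in range(w.space.num_loci)))
    return PotentialGame(game, tensor)


def _contract(tensor: np.ndarray, x: Sequence[np.ndarray], skip: int | None = None) -> np.ndarray:
    """Contract a payoff tensor with every player's mixed strategy.

    With ``skip=i`` player *i*'s axis is left free, yielding the vector of
    *i*'s expected payoffs per own action.
    """
    out = tensor
    # contract from the last axis down so earlier axis numbers stay valid
    for ax in reversed(range(tensor.ndim)):
        if ax == skip:
            continue
        out = np.tensordot(out, x[ax], axes=([ax], [0]))
    return out


def potential_value(g: PotentialGame, x: Sequence) -> float:
    """Multilinear extension of the potential at a mixed profile."""
    x = as_mixed_profile(g, x)
    return float(_contract(g.potential, x))


def expected_payoff(game: FiniteGame | PotentialGame, x: Sequence, player: int) -> float:
    base = game.game if isinstance(game, PotentialGame) else game
    x = as_mixed_profile(base, x)
    return float(_contract(base.payoffs[player], x))


def unilateral_payoffs(game: FiniteGame | PotentialGame, x: Sequence, player: int) -> np.ndarray:
    """Player's expected payoff for each own pure action against ``x_{-i}``."""
    base = game.game if isinstance(game, PotentialGame) else game
    x = as_mixed_profile(base, x)
    return np.asarray(_contract(base.payoffs[player], x, skip=player), dtype=float)


def enumerate_pure_nash(game: FiniteGame | PotentialGame) -> set[tuple[int, ...]]:
    """All pure profiles with no strictly improving unilateral deviation.

    Ties count as equilibria (weak inequality), so degenerate games may
    return plateaus.  For a potential game the result is the set of local
    maxima of the potential and is never empty.
    """
    base = game.game if isinstance(game, PotentialGame) else game
    nash: set[tuple[int, ...]] = set()
    for profile in base.profiles():
        ok = True
        for i, u in enumerate(base.payoffs):
            row = u[profile[:i] + (slice(None),) + profile[i + 1:]]
            if np.max(row) > row[profile[i]] + 0.0:
                ok = False
                break
        if ok:
            nash.add(profile)
    return nash


def find_potential(game: FiniteGame) -> PotentialGame | None:
    """Construct an exact potential, or return ``None`` if none exists.

    Φ is integrated along coordinate paths from the all-zeros profile
    (changing one player's action at a time and accumulating that player's
    payoff differences); the candidate is then checked on every unilateral
    edge.  Tolerance ``1e-9`` on payoff differences.
    """
    counts = game.action_counts
    phi = np.zeros(counts)
    for profile in game.profiles():
        val = 0.0
        current = [0] * len(counts)
        for i, a in enumerate(profile):
            if a == 0:
                continue
            before = tuple(current)
            current[i] = a
            after = tuple(current)
            val += game.payoffs[i][after] - game.payoffs[i][before]
        phi[profile] = val
    if _potential_defect(game, phi) > POTENTIAL_TOL:
        return None
    return PotentialGame(game, phi)


def best_reply_step(game: FiniteGame | PotentialGame, a: Sequence[int]) -> tuple[int, ...]:
    """Simultaneous best reply: every player switches to a best response
    against the others' current actions; ties broken by lowest action index."""
    base = game.game if isinstance(game, PotentialGame) else game
    a = tuple(int(ai) for ai in a)
    reply = []
    for i, u in enumerate(base.payoffs):
        row = u[a[:i] + (slice(None),) + a[i + 1:]]
        reply.append(int(np.argmax(row)))
    return tuple(reply)


def epsilon_nash_gap(game: FiniteGame | PotentialGame, x: Sequence) -> float:
    """Largest unilateral improvement any player can gain by deviating from x.

    Zero (up to tolerance) exactly at Nash equilibria; strictly positive
    elsewhere.
    """
    base = game.game if isinstance(game, PotentialGame) else game
    x = as_mixed_profile(base, x)
    gap = 0.0
    for i in range(base.num_players):
        payoffs = unilateral_payoffs(base, x, i)
        current = float(x[i] @ payoffs)
        gap = max(gap, float(np.max(payoffs) - current))
    return max(gap, 0.0)
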