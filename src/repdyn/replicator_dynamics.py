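"""Discrete-time step operators and the trajectory runner.

Every dynamic here is a map of a probability state to a probability state,
driven by the current fitness landscape:

* **asexual**: ``d⁺_g = d_g w_g / w̄`` on the genotype simplex — the
  discrete replicator, equivalently parameter-free multiplicative-weights
  updating with fitness as payoff;
* **haploid sexual**: the same update applied per locus to allelic
  frequencies, with the allele's *marginal* fitness (its conditional mean
  fitness under the linkage-equilibrium lift) as payoff;
* **genetic linkage**: λ-type reproduction (blocks of loci inherited
  intact) and convex mixtures of λ-dynamics over a recombination tuple,
  interpolating between asexual (coarsest partition) and free
  recombination (finest partition);
* **diploid**: single-locus allele-frequency replicator on a symmetric
  pair-fitness matrix, and the two-locus gamete recursion whose
  recombination residual is the linkage-disequilibrium term;
* **MWU / Hedge**: polynomial ``d_i(1+ηℓ_i)`` and exponential
  ``d_i e^{ηℓ_i}`` reweighting of arbitrary payoff vectors;
* **Baum–Eagon**: the gradient-reweighted simplex map
  ``q_ij⁺ ∝ q_ij ∂U/∂q_ij`` of a nonnegative-coefficient polynomial U,
  which increases U monotonically off fixed points and specialises to each
  of the replicator dynamics above for the right choice of U.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field
from functools import reduce
from typing import Sequence

import numpy as np

from .environments import EnvironmentProcess
from .genotype_core import (
    SIMPLEX_TOL,
    AllelicProfile,
    DimensionError,
    DiploidLandscape,
    ExtinctionError,
    FitnessLandscape,
    GameteState,
    GenotypeDistribution,
    GenotypeSpace,
    _as_simplex,
    lift_rho_inverse,
    mean_fitness,
    project_rho,
)
from .potential_games import FiniteGame, PotentialGame, as_mixed_profile, unilateral_payoffs

__all__ = [
    "StepSizeError",
    "DegenerateStateError",
    "Partition",
    "RecombinationTuple",
    "Trajectory",
    "SimplexPolynomial",
    "mean_fitness_polynomial",
    "diploid_mean_fitness_polynomial",
    "asexual_step",
    "mwu_polynomial_step",
    "mwu_exponential_step",
    "mwu_profile_step",
    "mwu_profile_orbit",
    "haploid_step",
    "t1_step",
    "lambda_step",
    "recombination_tuple_step",
    "diploid_single_step",
    "diploid_two_locus_step",
    "baum_eagon_step",
    "run_trajectory",
    "diploid_equilibria",
]

logger = logging.getLogger(__name__)


class StepSizeError(ValueError):
    """An MWU step size makes some updated weight non-positive."""


class DegenerateStateError(RuntimeError):
    """A Baum–Eagon denominator vanished (state on a degenerate face)."""


# ---------------------------------------------------------------------------
# linkage structures


@dataclass(frozen=True)
class Partition:
    """A partition of the locus set {0, …, m−1} into disjoint blocks.

    Loci in one block are physically linked: an offspring inherits the
    whole block from a single parent.
    """

    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        blocks = tuple(tuple(sorted(int(i) for i in b)) for b in self.blocks)
        blocks = tuple(sorted(blocks))
        if not blocks or any(not b for b in blocks):
            raise ValueError("partition blocks must be non-empty")
        flat = [i for b in blocks for i in b]
        if len(flat) != len(set(flat)):
            raise ValueError("partition blocks must be disjoint")
        if sorted(flat) != list(range(len(flat))):
            raise ValueError("partition blocks must cover 0..m-1 exactly")
        object.__setattr__(self, "blocks", blocks)

    @property
    def num_loci(self) -> int:
        return sum(len(b) for b in self.blocks)

    @classmethod
    def coarsest(cls, m: int) -> "Partition":
        return cls((tuple(range(m)),))

    @classmethod
    def finest(cls, m: int) -> "Partition":
        return cls(tuple((i,) for i in range(m)))


@dataclass
class RecombinationTuple:
    """Probability weights ``r_λ`` over locus partitions (they sum to 1)."""

    weights: dict[Partition, float]

    def __post_init__(self) -> None:
        w = {lam: float(r) for lam, r in self.weights.items()}
        if not w:
            raise ValueError("recombination tuple must contain at least one partition")
        if any(r < 0 for r in w.values()):
            raise ValueError("recombination weights must be non-negative")
        total = sum(w.values())
        if abs(total - 1.0) > SIMPLEX_TOL:
            raise ValueError(f"recombination weights sum to {total!r}, not 1")
        m = {lam.num_loci for lam in w}
        if len(m) != 1:
            raise ValueError("all partitions must be over the same locus set")
        self.weights = w

    @classmethod
    def two_point(cls, m: int, r: float) -> "RecombinationTuple":
        """The classic single-rate case: recombine (finest) with probability
        ``r``, clone (coarsest) with probability ``1−r``."""
        if not 0.0 <= r <= 1.0:
            raise ValueError("recombination rate must lie in [0, 1]")
        return cls({Partition.finest(m): r, Partition.coarsest(m): 1.0 - r})


# ---------------------------------------------------------------------------
# array kernels (private; the public ops wrap them with validation)


def _asexual_kernel(d: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    wbar = float(d @ w)
    if wbar <= 0.0:
        raise ExtinctionError("mean fitness is zero on the current support")
    out = d * w / wbar
    return out / out.sum(), wbar


def _haploid_kernel(freqs: Sequence[np.ndarray], wt: np.ndarray):
    d = reduce(np.multiply.outer, freqs)
    dw = d * wt
    wbar = float(dw.sum())
    if wbar <= 0.0:
        raise ExtinctionError("mean fitness is zero at the current allelic profile")
    m = dw.ndim
    new = []
    for i in range(m):
        axes = tuple(ax for ax in range(m) if ax != i)
        qi = dw.sum(axis=axes) if axes else dw.copy()
        qi = qi / wbar
        new.append(qi / qi.sum())
    return new, wbar


_LETTERS = string.ascii_lowercase


def _lambda_kernel(d: np.ndarray, w: np.ndarray, shape: tuple[int, ...], lam: Partition):
    post, wbar = _asexual_kernel(d, w)
    if len(lam.blocks) == 1:
        return post, wbar
    t = post.reshape(shape)
    m = t.ndim
    letters = _LETTERS[:m]
    subs, margs = [], []
    for block in lam.blocks:
        axes = tuple(ax for ax in range(m) if ax not in block)
        marg = t.sum(axis=axes) if axes else t
        margs.append(marg)
        subs.append("".join(letters[i] for i in block))
    out = np.einsum(",".join(subs) + "->" + letters, *margs).ravel()
    return out / out.sum(), wbar


def _diploid_single_kernel(p: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, float]:
    Wi = W @ p
    wbar = float(p @ Wi)
    if wbar <= 0.0:
        raise ExtinctionError("diploid mean fitness is zero")
    out = p * Wi / wbar
    return out / out.sum(), wbar


def _two_locus_kernel(x: np.ndarray, W: np.ndarray, shape: tuple[int, int], r: float):
    """Random union of gametes with recombination probability ``r``.

    Returns the next gamete frequencies, the implied per-gamete linkage
    disequilibrium ``D_g = x_g W_g / W̄ − x⁺_g`` and the mean fitness.
    """
    Wg = W @ x
    wbar = float(x @ Wg)
    if wbar <= 0.0:
        raise ExtinctionError("diploid mean fitness is zero")
    pair = np.outer(x, x) * W
    # axes after reshape: (i, l, k, j) for the gamete pair ((i,l), (k,j));
    # recombination swaps the locus-2 alleles, producing offspring (i, j)
    four = pair.reshape(shape + shape)
    rec = four.sum(axis=(1, 2)).ravel()
    xplus = ((1.0 - r) * x * Wg + r * rec) / wbar
    xplus = xplus / xplus.sum()
    D = x * Wg / wbar - xplus
    return xplus, D, wbar


# ---------------------------------------------------------------------------
# public step operators


def asexual_step(d: GenotypeDistribution, w: FitnessLandscape) -> GenotypeDistribution:
    """One generation of the asexual (clonal) replicator ``d⁺ = d·w/w̄``."""
    if d.space != w.space:
        raise DimensionError("distribution and landscape live on different spaces")
    out, _ = _asexual_kernel(d.weights, w.values)
    return GenotypeDistribution(d.space, out)


def mwu_polynomial_step(d, payoffs, eta: float | str) -> np.ndarray:
    """Polynomial MWU ``d⁺_i ∝ d_i(1+ηℓ_i)``.

    ``eta="parameter-free"`` gives the η→∞ limit ``d⁺_i ∝ d_i ℓ_i`` — the
    replicator equation itself — and then requires positive payoffs on the
    support.
    """
    d = _as_simplex(d, name="weights")
    ell = np.asarray(payoffs, dtype=float)
    if ell.shape != d.shape:
        raise DimensionError("payoff vector does not match the weight vector")
    support = d > 0
    if isinstance(eta, str):
        if eta != "parameter-free":
            raise ValueError(f"unknown eta mode {eta!r}")
        if np.any(ell[support] <= 0):
            raise StepSizeError("parameter-free MWU needs strictly positive payoffs on the support")
        factor = ell
    else:
        if eta <= 0:
            raise StepSizeError("eta must be positive")
        factor = 1.0 + float(eta) * ell
        if np.any(factor[support] <= 0):
            raise StepSizeError("step size too large: 1 + eta*payoff is non-positive on the support")
    num = d * factor
    return num / num.sum()


def mwu_exponential_step(d, payoffs, eta: float) -> np.ndarray:
    """Exponential MWU (Hedge) ``d⁺_i ∝ d_i e^{ηℓ_i}``.

    Shift-invariant in the payoffs; the maximum is subtracted before
    exponentiating so large payoffs cannot overflow.
    """
    d = _as_simplex(d, name="weights")
    ell = np.asarray(payoffs, dtype=float)
    if ell.shape != d.shape:
        raise DimensionError("payoff vector does not match the weight vector")
    if not np.all(np.isfinite(ell)):
        raise ValueError("payoffs must be finite")
    if eta <= 0:
        raise StepSizeError("eta must be positive")
    z = eta * ell
    num = d * np.exp(z - z.max())
    return num / num.sum()


def mwu_profile_step(
    game: FiniteGame | PotentialGame, x: Sequence, eta: float | str = "parameter-free"
) -> tuple[np.ndarray, ...]:
    """All players simultaneously apply polynomial MWU to their own strategy,
    each against the others' *current* mixed strategies."""
    base = game.game if isinstance(game, PotentialGame) else game
    x = as_mixed_profile(base, x)
    out = []
    for i in range(base.num_players):
        payoffs = unilateral_payoffs(base, x, i)
        out.append(mwu_polynomial_step(x[i], payoffs, eta))
    return tuple(out)


def mwu_profile_orbit(
    game: FiniteGame | PotentialGame,
    x0: Sequence,
    n_steps: int,
    eta: float | str = "parameter-free",
    tol: float = 0.0,
) -> tuple[tuple[np.ndarray, ...], int]:
    """Iterate :func:`mwu_profile_step`, carrying log-weights.

    The map is identical to repeated :func:`mwu_profile_step`; tracking
    ``log q`` keeps heavily-losing actions at finite log-weight instead of
    letting them underflow to an absorbing exact zero, so orbits that pass
    near a saddle can still leave it, as they do in exact arithmetic.
    Returns the final profile and the number of steps taken (stops early
    when successive profiles differ by less than ``tol`` in max norm).
    """
    base = game.game if isinstance(game, PotentialGame) else game
    x = as_mixed_profile(base, x0)
    logs = []
    for xi in x:
        if np.any(xi <= 0):
            raise StepSizeError("mwu_profile_orbit needs a full-support start")
        logs.append(np.log(xi))
    steps = 0
    for t in range(n_steps):
        weights = []
        for lq in logs:
            w = np.exp(lq - lq.max())
            weights.append(w / w.sum())
        new_logs = []
        delta = 0.0
        settled = True
        for i in range(base.num_players):
            ell = unilateral_payoffs(base, weights, i)
            # a near-vertex state is only final if the carried action is
            # also payoff-maximal; otherwise a suppressed action is still
            # climbing in log-weight and will eventually take over
            if ell[int(np.argmax(weights[i]))] < np.max(ell) - 1e-12:
                settled = False
            if isinstance(eta, str):
                if eta != "parameter-free":
                    raise ValueError(f"unknown eta mode {eta!r}")
                if np.any(ell < 0) or not np.any(ell > 0):
                    raise StepSizeError(
                        "parameter-free MWU needs nonnegative payoffs, some positive"
                    )
                with np.errstate(divide="ignore"):
                    lq = logs[i] + np.log(ell)  # zero payoff kills the action
            else:
                factor = 1.0 + float(eta) * ell
                if np.any(factor <= 0):
                    raise StepSizeError("step size too large for these payoffs")
                lq = logs[i] + np.log(factor)
            lq = lq - lq.max()
            new_logs.append(lq)
            w_new = np.exp(lq)
            w_new = w_new / w_new.sum()
            delta = max(delta, float(np.max(np.abs(w_new - weights[i]))))
        logs = new_logs
        steps = t + 1
        if delta < tol and settled:
            break
    final = []
    for lq in logs:
        w = np.exp(lq - lq.max())
        final.append(w / w.sum())
    return tuple(final), steps


def haploid_step(q: AllelicProfile, w: FitnessLandscape) -> AllelicProfile:
    """One generation of the haploid sexual replicator on allelic frequencies.

    Each allele is reweighted by its marginal fitness under the
    linkage-equilibrium lift of ``q``: ``q⁺_ij = q_ij w_ij / w̄``.
    """
    if q.space != w.space:
        raise DimensionError("profile and landscape live on different spaces")
    new, _ = _haploid_kernel(q.freqs, w.tensor)
    return AllelicProfile(q.space, tuple(new))


def t1_step(d: GenotypeDistribution, w: FitnessLandscape) -> GenotypeDistribution:
    """Haploid step seen on the genotype simplex: ``ρ⁻¹ ∘ τ ∘ ρ``.

    The output is always in linkage equilibrium.
    """
    return lift_rho_inverse(haploid_step(project_rho(d), w))


def lambda_step(d: GenotypeDistribution, w: FitnessLandscape, lam: Partition) -> GenotypeDistribution:
    """λ-type reproduction: selection followed by independent block inheritance.

    Selection maps ``d`` to ``d·w/w̄``; offspring then inherit each block of
    linked loci intact from a random parent, so the next generation is the
    product of the post-selection block marginals.  The coarsest partition
    recovers the asexual step, the finest the free-recombination step.
    """
    if d.space != w.space:
        raise DimensionError("distribution and landscape live on different spaces")
    if lam.num_loci != d.space.num_loci:
        raise DimensionError("partition is over a different number of loci")
    out, _ = _lambda_kernel(d.weights, w.values, d.space.shape, lam)
    return GenotypeDistribution(d.space, out)


def recombination_tuple_step(
    d: GenotypeDistribution, w: FitnessLandscape, r: RecombinationTuple
) -> GenotypeDistribution:
    """Mixture of λ-dynamics: ``d⁺ = Σ_λ r_λ T_λ(d)``."""
    acc = np.zeros(d.space.size)
    for lam, weight in r.weights.items():
        if weight == 0.0:
            continue
        out, _ = _lambda_kernel(d.weights, w.values, d.space.shape, lam)
        acc += weight * out
    return GenotypeDistribution(d.space, acc / acc.sum())


def diploid_single_step(p, W: DiploidLandscape) -> np.ndarray:
    """Single-locus diploid replicator ``p⁺_i = p_i W_i / W̄`` with
    ``W_i = Σ_j p_j W_ij`` the marginal fitness of allele i."""
    p = _as_simplex(p, name="allele frequencies")
    if p.size != W.num_alleles:
        raise DimensionError("frequency vector does not match the fitness matrix")
    out, _ = _diploid_single_kernel(p, W.values)
    return out


def diploid_two_locus_step(x: GameteState, r: float) -> tuple[GameteState, np.ndarray]:
    """Two-locus diploid gamete recursion with recombination rate ``r``.

    Random union of gametes; with probability ``r`` the offspring gamete
    swaps locus-2 alleles between its two parental gametes.  Returns the
    next state and the implied per-gamete linkage-disequilibrium term
    ``D_g = x_g W_g / W̄ − x⁺_g`` (identically zero at ``r = 0``).
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("recombination rate must lie in [0, 1]")
    xplus, D, _ = _two_locus_kernel(
        x.frequencies, x.pair_fitness.values, x.space.shape, float(r)
    )
    return GameteState(x.space, xplus, x.pair_fitness), D


# ---------------------------------------------------------------------------
# Baum–Eagon machinery


@dataclass
class SimplexPolynomial:
    """A polynomial with nonnegative coefficients in simplex variables q_ij.

    ``terms`` is a list of ``(coeff, monomial)`` pairs, where a monomial is
    a tuple of ``((locus, allele), power)`` factors.  ``var_counts`` gives
    the number of variables per locus/simplex.
    """

    var_counts: tuple[int, ...]
    terms: list[tuple[float, tuple[tuple[tuple[int, int], int], ...]]]

    def __post_init__(self) -> None:
        for coeff, mono in self.terms:
            if coeff < 0:
                raise ValueError("Baum–Eagon polynomials need nonnegative coefficients")
            for (i, j), power in mono:
                if not (0 <= i < len(self.var_counts) and 0 <= j < self.var_counts[i]):
                    raise DimensionError(f"variable q[{i}][{j}] outside the declared simplices")
                if power < 1:
                    raise ValueError("monomial powers must be positive integers")

    def value(self, freqs: Sequence[np.ndarray]) -> float:
        total = 0.0
        for coeff, mono in self.terms:
            v = coeff
            for (i, j), power in mono:
                v *= freqs[i][j] ** power
            total += v
        return total

    def gradient(self, freqs: Sequence[np.ndarray]) -> list[np.ndarray]:
        grads = [np.zeros(k) for k in self.var_counts]
        for coeff, mono in self.terms:
            for (i, j), power in mono:
                v = coeff * power * freqs[i][j] ** (power - 1)
                for (i2, j2), p2 in mono:
                    if (i2, j2) != (i, j):
                        v *= freqs[i2][j2] ** p2
                grads[i][j] += v
        return grads


def mean_fitness_polynomial(w: FitnessLandscape) -> SimplexPolynomial:
    """The multilinear mean-fitness polynomial ``Σ_g w_g Π_i q_{i,g_i}``."""
    terms = []
    for idx, g in enumerate(w.space.genotypes()):
        coeff = float(w.values[w.space.index(g)])
        if coeff != 0.0:
            terms.append((coeff, tuple(((i, a), 1) for i, a in enumerate(g))))
    return SimplexPolynomial(w.space.alleles_per_locus, terms)


def diploid_mean_fitness_polynomial(W: DiploidLandscape) -> SimplexPolynomial:
    """The quadratic ``W̄(p) = Σ_ij p_i p_j W_ij`` on a single simplex."""
    n = W.num_alleles
    terms = []
    for i in range(n):
        if W.values[i, i] != 0.0:
            terms.append((float(W.values[i, i]), (((0, i), 2),)))
        for j in range(i + 1, n):
            if W.values[i, j] != 0.0:
                terms.append((2.0 * float(W.values[i, j]), (((0, i), 1), ((0, j), 1))))
    return SimplexPolynomial((n,), terms)


def baum_eagon_step(q: AllelicProfile | Sequence[np.ndarray], U: SimplexPolynomial):
    """Baum–Eagon update ``q⁺_ij = q_ij (∂U/∂q_ij) / Σ_s q_is (∂U/∂q_is)``.

    By the Baum–Eagon inequality the update never decreases ``U``, with
    equality only at fixed points.  Accepts either an
    :class:`~repdyn.genotype_core.AllelicProfile` (returned as such) or a
    plain sequence of simplex vectors.
    """
    profile = isinstance(q, AllelicProfile)
    freqs = q.freqs if profile else tuple(_as_simplex(v, name="simplex vector") for v in q)
    if tuple(len(v) for v in freqs) != tuple(U.var_counts):
        raise DimensionError("state does not match the polynomial's simplices")
    grads = U.gradient(freqs)
    new = []
    for qi, gi in zip(freqs, grads):
        den = float(qi @ gi)
        if den <= 0.0:
            raise DegenerateStateError("Baum–Eagon denominator vanished")
        out = qi * gi / den
        new.append(out / out.sum())
    if profile:
        return AllelicProfile(q.space, tuple(new))
    return tuple(new)


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """A recorded orbit of one dynamic.

    ``mean_fitness[t]`` is the normaliser ``w̄^{t+1}`` of step ``t+1``, i.e.
    the mean fitness of the pre-step state under that step's landscape;
    for a fixed environment this sequence is the Lyapunov sequence of the
    dynamic.  ``states`` holds the state before step 1 and then every
    ``record_every``-th post-step state plus the final one.
    """

    dynamic: str
    states: list
    state_steps: list[int]
    mean_fitness: np.ndarray
    env_labels: list[str]
    n_steps: int
    stop_reason: str = "completed"
    final_step_delta: float = float("nan")

    @property
    def final_state(self):
        return self.states[-1]


def _state_vector(state) -> np.ndarray:
    if isinstance(state, GenotypeDistribution):
        return state.weights
    if isinstance(state, AllelicProfile):
        return state.stacked()
    if isinstance(state, GameteState):
        return state.frequencies
    return np.asarray(state, dtype=float)


class _Runner:
    """Adapter giving each dynamic a uniform (vector in, vector out) kernel."""

    def __init__(self, dynamic: str, init, **params):
        self.dynamic = dynamic
        self.params = params
        if dynamic == "asexual":
            self.space = init.space
            self.vec = init.weights.copy()
            self.step = lambda v, w: _asexual_kernel(v, w.values)
            self.wrap = lambda v: GenotypeDistribution(self.space, v)
        elif dynamic in ("haploid", "mwu_profile"):
            self.space = init.space
            self.freqs = [f.copy() for f in init.freqs]
            self.eta = params.get("eta", "parameter-free")
            self.wrap = lambda freqs: AllelicProfile(self.space, tuple(freqs))
        elif dynamic == "t1":
            self.space = init.space
            self.vec = init.weights.copy()

            def _t1(v, w):
                q = GenotypeDistribution(self.space, v)
                wbar = mean_fitness(q, w)
                return t1_step(q, w).weights, wbar

            self.step = _t1
            self.wrap = lambda v: GenotypeDistribution(self.space, v)
        elif dynamic == "lambda":
            self.space = init.space
            self.vec = init.weights.copy()
            lam = params["partition"]
            self.step = lambda v, w: _lambda_kernel(v, w.values, self.space.shape, lam)
            self.wrap = lambda v: GenotypeDistribution(self.space, v)
        elif dynamic == "tuple":
            self.space = init.space
            self.vec = init.weights.copy()
            rt: RecombinationTuple = params["recombination"]

            def _tuple(v, w):
                acc = np.zeros(v.size)
                wbar = float(v @ w.values)
                for lam, weight in rt.weights.items():
                    if weight == 0.0:
                        continue
                    out, wbar = _lambda_kernel(v, w.values, self.space.shape, lam)
                    acc += weight * out
                return acc / acc.sum(), wbar

            self.step = _tuple
            self.wrap = lambda v: GenotypeDistribution(self.space, v)
        elif dynamic == "diploid_single":
            self.vec = _as_simplex(init, name="allele frequencies")
            self.step = lambda v, W: _diploid_single_kernel(v, W.values)
            self.wrap = lambda v: v.copy()
        elif dynamic == "diploid_two_locus":
            self.space = init.space
            self.pair = init.pair_fitness
            self.vec = init.frequencies.copy()
            r = float(params.get("r", 0.5))

            def _two(v, W):
                pair = W if isinstance(W, DiploidLandscape) else self.pair
                out, _, wbar = _two_locus_kernel(v, pair.values, self.space.shape, r)
                return out, wbar

            self.step = _two
            self.wrap = lambda v: GameteState(self.space, v, self.pair)
        else:
            raise ValueError(f"unknown dynamic {dynamic!r}")

    # haploid / mwu_profile keep a list of simplices rather than one vector
    def is_profile(self) -> bool:
        return self.dynamic in ("haploid", "mwu_profile")

    def profile_step(self, freqs, w: FitnessLandscape):
        if self.dynamic == "haploid":
            return _haploid_kernel(freqs, w.tensor)
        # mwu_profile: polynomial MWU per locus on the identical-interests game
        d = reduce(np.multiply.outer, freqs)
        wt = w.tensor
        wbar = float((d * wt).sum())
        new = []
        m = len(freqs)
        for i in range(m):
            # expected payoff of each allele against the other loci
            other = reduce(
                np.multiply.outer, [freqs[j] for j in range(m) if j != i]
            ) if m > 1 else None
            if other is None:
                payoffs = wt
            else:
                payoffs = np.tensordot(
                    np.moveaxis(wt, i, 0), other, axes=(tuple(range(1, m)), tuple(range(m - 1)))
                )
            new.append(mwu_polynomial_step(freqs[i], payoffs, self.eta))
        return new, wbar


def run_trajectory(
    dynamic: str,
    init,
    env: EnvironmentProcess,
    n_steps: int,
    record_every: int = 1,
    stop_tol: float = 1e-14,
    **params,
) -> Trajectory:
    """Iterate a named dynamic under an environment process.

    The environment supplies the landscape for each generation; states,
    per-step mean fitness and environment labels are recorded.  Iteration
    stops early when successive states differ by less than ``stop_tol`` in
    max norm (``stop_reason = "fixed_point"``).  Deterministic given the
    environment's seed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    from .environments import realize  # local import to keep module load cheap

    runner = _Runner(dynamic, init, **params)
    realization = realize(env, n_steps)
    # mean fitness is a Lyapunov function for these dynamics under a fixed
    # landscape; a drop there is numerically noteworthy, not fatal
    monotone_expected = env.mode == "fixed" and dynamic in (
        "asexual", "haploid", "t1", "lambda", "tuple", "diploid_single"
    )
    prev_wbar = -np.inf

    states = [init]
    state_steps = [0]
    fitness: list[float] = []
    labels: list[str] = []
    stop_reason = "completed"
    delta = float("nan")

    if runner.is_profile():
        freqs = runner.freqs
        for t, (label, w) in enumerate(realization, start=1):
            try:
                new, wbar = runner.profile_step(freqs, w)
            except Exception as exc:
                raise type(exc)(f"step {t}: {exc}") from exc
            fitness.append(wbar)
            labels.append(label)
            if monotone_expected and wbar < prev_wbar - 1e-12:
                logger.warning("mean fitness decreased at step %d (%r -> %r)", t, prev_wbar, wbar)
            prev_wbar = wbar
            delta = max(
                float(np.max(np.abs(a - b))) for a, b in zip(new, freqs)
            )
            freqs = new
            if t % record_every == 0:
                states.append(runner.wrap([f.copy() for f in freqs]))
                state_steps.append(t)
            if delta < stop_tol:
                stop_reason = "fixed_point"
                break
        final = runner.wrap([f.copy() for f in freqs])
    else:
        vec = runner.vec
        for t, (label, w) in enumerate(realization, start=1):
            try:
                new, wbar = runner.step(vec, w)
            except Exception as exc:
                raise type(exc)(f"step {t}: {exc}") from exc
            fitness.append(wbar)
            labels.append(label)
            if monotone_expected and wbar < prev_wbar - 1e-12:
                logger.warning("mean fitness decreased at step %d (%r -> %r)", t, prev_wbar, wbar)
            prev_wbar = wbar
            delta = float(np.max(np.abs(new - vec)))
            vec = new
            if t % record_every == 0:
                states.append(runner.wrap(vec))
                state_steps.append(t)
            if delta < stop_tol:
                stop_reason = "fixed_point"
                break
        final = runner.wrap(vec)

    steps_run = len(fitness)
    if state_steps[-1] != steps_run:
        states.append(final)
        state_steps.append(steps_run)
    return Trajectory(
        dynamic=dynamic,
        states=states,
        state_steps=state_steps,
        mean_fitness=np.asarray(fitness),
        env_labels=labels,
        n_steps=steps_run,
        stop_reason=stop_reason,
        final_step_delta=delta,
    )


# ---------------------------------------------------------------------------
# diploid single-locus equilibria (support enumeration)


def diploid_equilibria(
    W: DiploidLandscape, *, seed: int = 0, perturbation: float = 1e-8, n_probes: int = 200
) -> list[dict]:
    """All simplex equilibria of the single-locus diploid replicator.

    For each allele support the linear marginal-fitness-equalisation system
    ``(W p)_i = c`` on the support, ``Σ p = 1`` is solved; solutions inside
    the simplex are kept and classified as ``stable`` when ``W̄`` has a
    strict local maximum there (random perturbation probing at the given
    step size), else ``unstable``.  Feasible for modest allele counts.
    """
    n = W.num_alleles
    rng = np.random.default_rng(seed)
    found: list[dict] = []
    for size in range(1, n + 1):
        for support in itertools.combinations(range(n), size):
            S = list(support)
            if size == 1:
                p = np.zeros(n)
                p[S[0]] = 1.0
            else:
                A = np.zeros((size + 1, size + 1))
                b = np.zeros(size + 1)
                A[:size, :size] = W.values[np.ix_(S, S)]
                A[:size, size] = -1.0
                A[size, :size] = 1.0
                b[size] = 1.0
                try:
                    sol = np.linalg.solve(A, b)
                except np.linalg.LinAlgError:
                    continue
                pS = sol[:size]
                if np.any(pS < -1e-10):
                    continue
                p = np.zeros(n)
                p[S] = np.clip(pS, 0.0, None)
                p = p / p.sum()
            if any(np.max(np.abs(p - e["p"])) < 1e-9 for e in found):
                continue
            wbar = float(p @ W.values @ p)
            stable = True
            for _ in range(n_probes):
                xi = rng.standard_normal(n)
                xi[p <= 0] = np.abs(xi[p <= 0])  # stay inside the simplex
                xi -= xi.mean()
                norm = np.max(np.abs(xi))
                if norm == 0:
                    continue
                q = p + perturbation * xi / norm
                q = np.clip(q, 0.0, None)
                q = q / q.sum()
                if float(q @ W.values @ q) > wbar + 1e-15:
                    stable = False
                    break
            found.append(
                {
                    "p": p,
                    "support": tuple(S),
                    "mean_fitness": wbar,
                    "kind": "pure" if size == 1 else "mixed",
                    "stability": "stable" if stable else "unstable",
                }
            )
    return found
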