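"""Convergence classification, regret, virtual convergence, basins and rates.

Diagnostics operate on recorded :class:`~repdyn.replicator_dynamics.Trajectory`
objects.  Distances are max-norm on the natural state coordinates (genotype
weights, or per-locus stacked allele frequencies): both "near a vertex" and
"per-locus monomorphic" are max-norm statements.

Two tolerances play different roles and are kept separate: a fixed-point
tolerance (default 1e-9) deciding whether the state has stopped moving, and
a vertex/ε-Nash tolerance (default 1e-6) deciding whether the stationary
state is monomorphic.  Conflating them misclassifies slow passages near
interior saddles.
"""

from __future__ import annotations

import json
import math
from functools import reduce
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .genotype_core import (
    AllelicProfile,
    FitnessLandscape,
    GameteState,
    GenotypeDistribution,
    GenotypeSpace,
    lift_rho_inverse,
    project_rho,
)
from .potential_games import enumerate_pure_nash, game_from_landscape
from .replicator_dynamics import Trajectory, _state_vector, run_trajectory
from .environments import EnvironmentProcess

__all__ = [
    "ConvergenceReport",
    "RegretRecord",
    "BasinMap",
    "classify_convergence",
    "monotonicity_check",
    "regret_report",
    "virtual_convergence_gap",
    "basin_map",
    "exponential_rate",
]

FIXED_POINT_TOL = 1e-9
VERTEX_TOL = 1e-6


@dataclass
class ConvergenceReport:
    """Outcome of a convergence classification.

    ``monomorphic``: the final state is (per locus) within tolerance of a
    vertex; ``polymorphic``: the state has stopped moving but some locus
    stays mixed; ``none``: still moving.
    """

    status: str
    limit_state: list
    limiting_mean_fitness: float
    per_locus_max_weight: list[float]
    steps: int
    tol: float
    fixed_point_tol: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class RegretRecord:
    """Cumulative regret against the best fixed vertex in hindsight."""

    horizon: int
    best_vertex: tuple[int, ...] | int
    best_cumulative: float
    realized_cumulative: float
    regret: float
    average_regret: float
    mode: str

    def to_json(self) -> str:
        d = asdict(self)
        d["best_vertex"] = list(self.best_vertex) if isinstance(self.best_vertex, tuple) else self.best_vertex
        return json.dumps(d, indent=2)


@dataclass
class BasinMap:
    """Empirical basins of attraction from random restarts."""

    entries: list[dict]
    counts: dict[str, int]
    fractions: dict[str, float]
    seed: int

    def to_tsv(self) -> str:
        lines = ["sample\tlabel\tsteps\tinit"]
        for i, e in enumerate(self.entries):
            init = ",".join(repr(x) for x in np.asarray(e["init"]).ravel())
            lines.append(f"{i}\t{e['label']}\t{e['steps']}\t{init}")
        return "\n".join(lines) + "\n"


def _per_locus_vectors(state) -> list[np.ndarray]:
    if isinstance(state, AllelicProfile):
        return list(state.freqs)
    if isinstance(state, GenotypeDistribution):
        return [state.weights]
    if isinstance(state, GameteState):
        return [state.frequencies]
    return [np.asarray(state, dtype=float)]


def classify_convergence(
    traj: Trajectory, tol: float = VERTEX_TOL, fixed_point_tol: float = FIXED_POINT_TOL
) -> ConvergenceReport:
    """Classify a trajectory as monomorphic, polymorphic or non-convergent."""
    if len(traj.states) < 2:
        raise ValueError("need at least two recorded states to classify")
    final = traj.final_state
    vecs = _per_locus_vectors(final)
    maxima = [float(np.max(v)) for v in vecs]
    moving = not (traj.final_step_delta < fixed_point_tol)
    if all(m >= 1.0 - tol for m in maxima) and not moving:
        status = "monomorphic"
    elif not moving:
        status = "polymorphic"
    else:
        status = "none"
    return ConvergenceReport(
        status=status,
        limit_state=[v.tolist() for v in vecs],
        limiting_mean_fitness=float(traj.mean_fitness[-1]) if len(traj.mean_fitness) else float("nan"),
        per_locus_max_weight=maxima,
        steps=traj.n_steps,
        tol=tol,
        fixed_point_tol=fixed_point_tol,
    )


def monotonicity_check(traj: Trajectory, tol: float = 1e-12) -> tuple[bool, int | None]:
    """Is the recorded mean-fitness sequence nondecreasing?

    Returns ``(True, None)`` or ``(False, first_violation_index)``.  Only
    meaningful for fixed-environment trajectories, where mean fitness is a
    Lyapunov function of the replicator-type dynamics.
    """
    f = traj.mean_fitness
    drops = np.flatnonzero(np.diff(f) < -tol)
    if drops.size:
        return False, int(drops[0])
    return True, None


def _log_fitness_columns(realization, space: GenotypeSpace) -> np.ndarray:
    mats = np.asarray([w.values for _, w in realization])
    if np.any(mats <= 0):
        raise ValueError("log-growth regret undefined with zero fitness values")
    return np.log(mats)  # (T, G)


def regret_report(
    traj: Trajectory, realization: Sequence, mode: str = "log-growth"
) -> RegretRecord:
    """Regret of the realised trajectory against the best fixed genotype.

    In ``log-growth`` mode the per-step payoff of the population is
    ``ln w̄^t`` (its realised log growth rate) and the benchmark is the
    genotype vertex maximising cumulative log fitness — the optimal
    genotype in hindsight.  ``linear`` mode uses raw fitness instead.
    For any asexual trajectory the log-growth regret is bounded by
    ``−ln(min_g d⁰_g)`` for every environment realization.
    """
    n = traj.n_steps
    realization = list(realization)[:n]
    space = _trajectory_space(traj)
    if mode == "log-growth":
        logw = _log_fitness_columns(realization, space)
        cums = logw.sum(axis=0)
        realized = float(np.sum(np.log(traj.mean_fitness[:n])))
    elif mode == "linear":
        cums = np.asarray([w.values for _, w in realization]).sum(axis=0)
        realized = float(np.sum(traj.mean_fitness[:n]))
    else:
        raise ValueError(f"unknown regret mode {mode!r}")
    best_idx = int(np.argmax(cums))
    best = float(cums[best_idx])
    regret = best - realized
    return RegretRecord(
        horizon=n,
        best_vertex=space.genotype(best_idx),
        best_cumulative=best,
        realized_cumulative=realized,
        regret=regret,
        average_regret=regret / n,
        mode=mode,
    )


def _trajectory_space(traj: Trajectory) -> GenotypeSpace:
    state = traj.states[0]
    if isinstance(state, (GenotypeDistribution, AllelicProfile, GameteState)):
        return state.space
    # bare vector states (diploid single locus): treat as one locus
    return GenotypeSpace((len(np.asarray(state).ravel()),))


def virtual_convergence_gap(
    traj: Trajectory, realization: Sequence, per_locus: bool = False
):
    """Finite-horizon virtual-convergence gap.

    Genotype level: ``|(1/n) Σ_t ln w_{g*}^t − (1/n) Σ_t ln w̄^t|`` with
    ``g*`` the best genotype in hindsight — the average-regret magnitude.
    Returns ``(gap, g*)``.

    Per-locus mode measures each locus against its best allele in
    hindsight under the *internal environment* (the realised frequencies
    of the other loci): the allele payoff at time t is its marginal
    fitness.  Requires states recorded every step.  Returns
    ``(gaps_per_locus, best_alleles)``.
    """
    n = traj.n_steps
    realization = list(realization)[:n]
    if not per_locus:
        rec = regret_report(traj, realization, mode="log-growth")
        return abs(rec.average_regret), rec.best_vertex

    if traj.state_steps != list(range(len(traj.states))):
        raise ValueError("per-locus gaps need record_every=1 trajectories")
    space = _trajectory_space(traj)
    m = space.num_loci
    realized = np.log(traj.mean_fitness[:n])
    # allele payoff per step: marginal fitness given the other loci's freqs
    cums = [np.zeros(k) for k in space.alleles_per_locus]
    for t, (_, w) in enumerate(realization):
        state = traj.states[t]
        q = state if isinstance(state, AllelicProfile) else project_rho(state)
        wt = w.tensor
        for i in range(m):
            # allele payoff against the internal environment: contract the
            # fitness tensor with the other loci's current frequencies
            # (independent of q_i, defined even for extinct alleles)
            if m == 1:
                wij = wt.astype(float)
            else:
                other = reduce(
                    np.multiply.outer, [q.freqs[j] for j in range(m) if j != i]
                )
                wij = np.tensordot(
                    np.moveaxis(wt, i, 0), other,
                    axes=(tuple(range(1, m)), tuple(range(m - 1))),
                )
            if np.any(wij <= 0):
                raise ValueError("per-locus log payoffs undefined at zero fitness")
            cums[i] += np.log(wij)
    avg_realized = float(realized.mean())
    gaps = []
    bests = []
    for i in range(m):
        j = int(np.argmax(cums[i]))
        bests.append(j)
        gaps.append(abs(float(cums[i][j]) / n - avg_realized))
    return np.asarray(gaps), tuple(bests)


def basin_map(
    landscape: FitnessLandscape,
    dynamic: str,
    n_samples: int,
    seed: int,
    tol: float = VERTEX_TOL,
    n_steps: int = 20_000,
    **params,
) -> BasinMap:
    """Empirical basins of attraction under a fixed landscape.

    Initial states are sampled per-locus Dirichlet(1,…,1) (uniform on each
    simplex, or on the genotype simplex for genotype-level dynamics), run
    to convergence and labelled by the pure Nash genotype they fixed on;
    stationary mixed limits are labelled ``"mixed"`` and non-converged
    samples ``"none"`` (never dropped).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    space = landscape.space
    env = EnvironmentProcess.fixed(landscape)
    nash = enumerate_pure_nash(game_from_landscape(landscape))
    entries = []
    for _ in range(n_samples):
        if dynamic in ("haploid", "mwu_profile"):
            init = AllelicProfile(
                space, tuple(rng.dirichlet(np.ones(k)) for k in space.alleles_per_locus)
            )
        else:
            init = GenotypeDistribution(space, rng.dirichlet(np.ones(space.size)))
        traj = run_trajectory(dynamic, init, env, n_steps, record_every=n_steps, **params)
        report = classify_convergence(traj, tol=tol)
        if report.status == "monomorphic":
            vecs = _per_locus_vectors(traj.final_state)
            if isinstance(traj.final_state, AllelicProfile):
                profile = tuple(int(np.argmax(v)) for v in vecs)
            else:
                profile = space.genotype(int(np.argmax(vecs[0])))
            label = str(profile) if profile in nash else f"non-nash {profile}"
        elif report.status == "polymorphic":
            label = "mixed"
        else:
            label = "none"
        entries.append({"init": _state_vector(init).tolist(), "label": label, "steps": traj.n_steps})
    counts: dict[str, int] = {}
    for e in entries:
        counts[e["label"]] = counts.get(e["label"], 0) + 1
    fractions = {k: v / n_samples for k, v in counts.items()}
    return BasinMap(entries=entries, counts=counts, fractions=fractions, seed=seed)


def exponential_rate(
    traj: Trajectory, limit_state, tail_fraction: float = 0.2
) -> float:
    """Local exponential convergence rate towards a limit state.

    Least-squares slope of ``ln(max-norm distance to limit)`` against the
    step index over the trajectory tail; a negative slope certifies locally
    exponential convergence.  ``-inf`` signals exact (to machine precision)
    convergence inside the tail; ``nan`` signals no contracting movement.
    """
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError("tail_fraction must be in (0, 1]")
    limit = _state_vector(limit_state)
    steps = np.asarray(traj.state_steps, dtype=float)
    dists = np.asarray(
        [float(np.max(np.abs(_state_vector(s) - limit))) for s in traj.states]
    )
    k = max(2, int(math.ceil(len(dists) * tail_fraction)))
    tail_d = dists[-k:]
    tail_t = steps[-k:]
    if np.any(tail_d == 0.0):
        return float("-inf")
    if np.allclose(tail_d, tail_d[0], rtol=1e-12, atol=0.0):
        return float("nan")
    slope = np.polyfit(tail_t, np.log(tail_d), 1)[0]
    return float(slope)
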