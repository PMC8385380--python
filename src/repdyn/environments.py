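"""Environment processes: one fitness landscape per generation.

Temporally varying selection is modelled by a process that emits a fitness
landscape each generation.  Supported modes:

``fixed``
    the same landscape forever;
``schedule``
    an explicit (cycled) sequence of landscape indices — periodic
    environments are the canonical use;
``iid``
    independent draws from a probability vector over the landscape set;
``markov``
    a finite-state Markov chain over the landscape set;
``callback``
    an arbitrary user function ``t -> landscape index``.

Realisations are deterministic given the seed.  The module also computes
the average one-step-ahead expected log-fitness statistic
``ρ̂_t^g = (1/t) Σ_{s≤t} E[ln w_g(ψ_{s+1}) | ψ_s]`` used to predict which
genotype an asexual population will fix on, and the tail-window dominance
check for asymptotic one-step-ahead superiority.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .genotype_core import DiploidLandscape, FitnessLandscape, SIMPLEX_TOL

__all__ = [
    "EnvironmentProcess",
    "LogFitnessPanel",
    "realize",
    "log_fitness_panel",
    "one_step_ahead_average",
    "one_step_ahead_series",
    "empirical_one_step_series",
    "superiority_check",
]

Landscape = FitnessLandscape | DiploidLandscape

_MODES = ("fixed", "schedule", "iid", "markov", "callback")


def _label(w: Landscape, idx: int) -> str:
    return w.label if w.label is not None else f"env{idx}"


@dataclass
class EnvironmentProcess:
    """Seeded generator of per-generation fitness landscapes."""

    mode: str
    landscapes: tuple[Landscape, ...]
    schedule: tuple[int, ...] | None = None
    probs: np.ndarray | None = None
    transition: np.ndarray | None = None
    initial: np.ndarray | None = None
    seed: int = 0
    callback: Callable[[int], int] | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown environment mode {self.mode!r}")
        self.landscapes = tuple(self.landscapes)
        if not self.landscapes:
            raise ValueError("environment needs at least one landscape")
        spaces = {
            w.space if isinstance(w, FitnessLandscape) else ("diploid", w.num_alleles)
            for w in self.landscapes
        }
        if len(spaces) != 1:
            raise ValueError("all landscapes in an environment must share one space")
        n = len(self.landscapes)
        if self.mode == "schedule":
            if not self.schedule:
                raise ValueError("schedule mode needs a non-empty schedule")
            self.schedule = tuple(int(i) for i in self.schedule)
            if any(i < 0 or i >= n for i in self.schedule):
                raise ValueError("schedule indexes outside the landscape set")
        if self.mode == "iid":
            p = np.asarray(self.probs, dtype=float)
            if p.shape != (n,) or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                raise ValueError("iid mode needs a probability vector over the landscapes")
            self.probs = p / p.sum()
        if self.mode == "markov":
            P = np.asarray(self.transition, dtype=float)
            if P.shape != (n, n) or np.any(P < 0) or np.max(np.abs(P.sum(axis=1) - 1)) > 1e-9:
                raise ValueError("markov mode needs a row-stochastic transition matrix")
            self.transition = P / P.sum(axis=1, keepdims=True)
            if self.initial is None:
                init = np.zeros(n)
                init[0] = 1.0
            else:
                init = np.asarray(self.initial, dtype=float)
                if init.shape != (n,) or abs(init.sum() - 1.0) > 1e-9 or np.any(init < 0):
                    raise ValueError("markov initial distribution is not a probability vector")
            self.initial = init / init.sum()
        if self.mode == "callback" and self.callback is None:
            raise ValueError("callback mode needs a callback")

    # -- constructors -------------------------------------------------------

    @classmethod
    def fixed(cls, w: Landscape) -> "EnvironmentProcess":
        return cls(mode="fixed", landscapes=(w,))

    @classmethod
    def from_schedule(
        cls, landscapes: Sequence[Landscape], schedule: Sequence[int]
    ) -> "EnvironmentProcess":
        return cls(mode="schedule", landscapes=tuple(landscapes), schedule=tuple(schedule))

    @classmethod
    def iid(
        cls, landscapes: Sequence[Landscape], probs: Sequence[float], seed: int = 0
    ) -> "EnvironmentProcess":
        return cls(mode="iid", landscapes=tuple(landscapes), probs=np.asarray(probs), seed=seed)

    @classmethod
    def markov(
        cls,
        landscapes: Sequence[Landscape],
        transition: Sequence[Sequence[float]],
        initial: Sequence[float] | None = None,
        seed: int = 0,
    ) -> "EnvironmentProcess":
        return cls(
            mode="markov",
            landscapes=tuple(landscapes),
            transition=np.asarray(transition),
            initial=None if initial is None else np.asarray(initial),
            seed=seed,
        )

    # -- realisation --------------------------------------------------------

    def realize_indices(self, n: int) -> np.ndarray:
        """Landscape index for each generation ``t = 1..n`` (seed-deterministic)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if self.mode == "fixed":
            return np.zeros(n, dtype=int)
        if self.mode == "schedule":
            period = len(self.schedule)
            return np.asarray([self.schedule[t % period] for t in range(n)], dtype=int)
        if self.mode == "callback":
            return np.asarray([int(self.callback(t)) for t in range(n)], dtype=int)
        rng = np.random.default_rng(self.seed)
        k = len(self.landscapes)
        if self.mode == "iid":
            return rng.choice(k, size=n, p=self.probs)
        # markov
        out = np.empty(n, dtype=int)
        state = int(rng.choice(k, p=self.initial))
        for t in range(n):
            out[t] = state
            state = int(rng.choice(k, p=self.transition[state]))
        return out

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution (iid: μ itself; markov: left eigenvector)."""
        if self.mode == "iid":
            return self.probs.copy()
        if self.mode != "markov":
            raise ValueError("stationary distribution defined for iid/markov modes only")
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def realize(env: EnvironmentProcess, n: int) -> list[tuple[str, Landscape]]:
    """The realised environment sequence as ``(label, landscape)`` pairs."""
    idx = env.realize_indices(n)
    return [(_label(env.landscapes[i], i), env.landscapes[i]) for i in idx]


# ---------------------------------------------------------------------------
# one-step-ahead expected log-fitness (Definition-style statistics)


@dataclass
class LogFitnessPanel:
    """Per-genotype realised log-fitness series ``ln w_g(ψ_t)``.

    ``values`` has shape ``(T, G)``; ``indices`` is the realised landscape
    index sequence when available.
    """

    values: np.ndarray
    indices: np.ndarray | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("log-fitness panel must be 2-d (time x genotype)")
        if not np.all(np.isfinite(v)):
            raise ValueError("log fitness requires strictly positive fitness throughout")
        self.values = v


def log_fitness_panel(env: EnvironmentProcess, n: int) -> LogFitnessPanel:
    """Realise the environment and record ``ln w_g`` for every genotype."""
    idx = env.realize_indices(n)
    mats = np.asarray([w.values for w in env.landscapes])  # (K, G)
    if np.any(mats <= 0):
        raise ValueError("log fitness undefined: some landscape has zero-fitness genotypes")
    logs = np.log(mats)
    return LogFitnessPanel(
        values=logs[idx],
        indices=idx,
        labels=tuple(_label(w, i) for i, w in enumerate(env.landscapes)),
    )


def _log_fitness_matrix(env: EnvironmentProcess) -> np.ndarray:
    mats = np.asarray([w.values for w in env.landscapes])
    if np.any(mats <= 0):
        raise ValueError("log fitness undefined: some landscape has zero-fitness genotypes")
    return np.log(mats)


def one_step_ahead_average(
    env: EnvironmentProcess, realization: Sequence[int], g: int, t: int
) -> float:
    """``ρ̂_t^g``: running average of next-step conditional expected log fitness.

    Computable in closed form for ``fixed``, ``iid`` (where it is the
    constant ``Σ_ω μ(ω) ln w_g(ω)``) and ``markov`` modes (conditioning on
    the current chain state by the Markov property).  Other modes raise;
    use :func:`empirical_one_step_series` as a plug-in estimator instead.
    """
    series = one_step_ahead_series(env, realization, t)
    return float(series[t - 1, g])


def one_step_ahead_series(
    env: EnvironmentProcess, realization: Sequence[int], horizon: int
) -> np.ndarray:
    """``ρ̂_t^g`` for ``t = 1..horizon`` and all genotypes; shape ``(horizon, G)``."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    idx = np.asarray(realization, dtype=int)
    if idx.size < horizon:
        raise ValueError("realization shorter than requested horizon")
    logs = _log_fitness_matrix(env)  # (K, G)
    if env.mode == "fixed":
        cond = np.broadcast_to(logs[0], (horizon, logs.shape[1]))
    elif env.mode == "iid":
        const = env.probs @ logs
        cond = np.broadcast_to(const, (horizon, logs.shape[1]))
    elif env.mode == "markov":
        expect_next = env.transition @ logs  # (K, G): E[ln w | current state]
        cond = expect_next[idx[:horizon]]
    else:
        raise ValueError(
            f"one-step-ahead expectation unsupported for mode {env.mode!r}; "
            "use empirical_one_step_series"
        )
    csum = np.cumsum(cond, axis=0)
    t = np.arange(1, horizon + 1)[:, None]
    return csum / t


def empirical_one_step_series(panel: LogFitnessPanel) -> np.ndarray:
    """Plug-in estimator of ``ρ̂_t^g``: realised ``ln w_g(ψ_{s+1})`` in place
    of its conditional expectation, running-averaged.  Shape ``(T-1, G)``."""
    nxt = panel.values[1:]
    csum = np.cumsum(nxt, axis=0)
    t = np.arange(1, nxt.shape[0] + 1)[:, None]
    return csum / t


def superiority_check(rho_hat: np.ndarray, window: int) -> int | None:
    """Finite-horizon test of asymptotic one-step-ahead superiority.

    Returns the genotype whose ``ρ̂`` series' tail-window minimum strictly
    exceeds every other genotype's tail-window maximum, or ``None`` if no
    genotype dominates (e.g. when the series interleave, as they do for the
    alternating periodic counterexample).  A single-genotype space is
    vacuously superior.
    """
    r = np.asarray(rho_hat, dtype=float)
    if r.ndim != 2:
        raise ValueError("rho_hat must be 2-d (time x genotype)")
    T, G = r.shape
    if G == 1:
        return 0
    if T <= window:
        raise ValueError("series length must exceed the window")
    tail = r[-window:]
    lo = tail.min(axis=0)
    hi = tail.max(axis=0)
    for g in range(G):
        others = np.delete(hi, g)
        if lo[g] > np.max(others):
            return g
    return None
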