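"""JSON/TSV serialisation for landscapes, environments and trajectories.

Landscape JSON schema::

    {"loci": m, "alleles": [k_1, ..., k_m],
     "fitness": [...],        # row-major genotype order
     "label": "optional"}

Diploid JSON schema::

    {"alleles": n, "W": [[...], ...], "label": "optional"}

Environment JSON mirrors :class:`~repdyn.environments.EnvironmentProcess`.
Trajectory TSV columns are ``t``, ``env_label``, ``mean_fitness`` and the
state coordinates in row-major order; floats are written at repr precision
so round trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .environments import EnvironmentProcess
from .genotype_core import (
    AllelicProfile,
    DimensionError,
    DiploidLandscape,
    FitnessLandscape,
    GenotypeDistribution,
    GenotypeSpace,
)
from .replicator_dynamics import Trajectory, _state_vector

__all__ = [
    "ParseError",
    "load_landscape",
    "save_landscape",
    "load_diploid_landscape",
    "save_diploid_landscape",
    "load_environment",
    "save_environment",
    "trajectory_tsv",
    "save_trajectory",
]


class ParseError(ValueError):
    """A serialised object violates its schema."""


def _require(obj: dict, key: str, kind=None):
    if key not in obj:
        raise ParseError(f"missing required field {key!r}")
    val = obj[key]
    if kind is not None and not isinstance(val, kind):
        raise ParseError(f"field {key!r} has wrong type {type(val).__name__}")
    return val


def landscape_to_dict(w: FitnessLandscape) -> dict:
    d = {
        "loci": w.space.num_loci,
        "alleles": list(w.space.alleles_per_locus),
        "fitness": [float(v) for v in w.values],
    }
    if w.label is not None:
        d["label"] = w.label
    return d


def landscape_from_dict(obj: dict) -> FitnessLandscape:
    loci = _require(obj, "loci", int)
    alleles = _require(obj, "alleles", list)
    fitness = _require(obj, "fitness", list)
    if len(alleles) != loci:
        raise ParseError(f"field 'alleles' lists {len(alleles)} loci but 'loci' is {loci}")
    space = GenotypeSpace(tuple(int(k) for k in alleles))
    if len(fitness) != space.size:
        raise DimensionError(
            f"field 'fitness' has {len(fitness)} values for {space.size} genotypes"
        )
    return FitnessLandscape(space, np.asarray(fitness, dtype=float), label=obj.get("label"))


def load_landscape(path) -> FitnessLandscape:
    with open(path) as fh:
        return landscape_from_dict(json.load(fh))


def save_landscape(w: FitnessLandscape, path) -> None:
    Path(path).write_text(json.dumps(landscape_to_dict(w), indent=2) + "\n")


def diploid_to_dict(W: DiploidLandscape) -> dict:
    d = {"alleles": W.num_alleles, "W": [[float(v) for v in row] for row in W.values]}
    if W.label is not None:
        d["label"] = W.label
    return d


def diploid_from_dict(obj: dict) -> DiploidLandscape:
    n = _require(obj, "alleles", int)
    W = np.asarray(_require(obj, "W", list), dtype=float)
    if W.shape != (n, n):
        raise ParseError(f"field 'W' has shape {W.shape}, expected ({n}, {n})")
    return DiploidLandscape(W, label=obj.get("label"))


def load_diploid_landscape(path) -> DiploidLandscape:
    with open(path) as fh:
        return diploid_from_dict(json.load(fh))


def save_diploid_landscape(W: DiploidLandscape, path) -> None:
    Path(path).write_text(json.dumps(diploid_to_dict(W), indent=2) + "\n")


def environment_to_dict(env: EnvironmentProcess) -> dict:
    d: dict = {"mode": env.mode, "seed": env.seed, "landscapes": []}
    for w in env.landscapes:
        if isinstance(w, FitnessLandscape):
            d["landscapes"].append(landscape_to_dict(w))
        else:
            d["landscapes"].append(diploid_to_dict(w))
    if env.schedule is not None:
        d["schedule"] = list(env.schedule)
    if env.probs is not None:
        d["probs"] = [float(p) for p in env.probs]
    if env.transition is not None:
        d["transition"] = [[float(p) for p in row] for row in env.transition]
        d["initial"] = [float(p) for p in env.initial]
    return d


def environment_from_dict(obj: dict) -> EnvironmentProcess:
    mode = _require(obj, "mode", str)
    raw = _require(obj, "landscapes", list)
    landscapes = []
    for item in raw:
        if "W" in item:
            landscapes.append(diploid_from_dict(item))
        else:
            landscapes.append(landscape_from_dict(item))
    return EnvironmentProcess(
        mode=mode,
        landscapes=tuple(landscapes),
        schedule=tuple(obj["schedule"]) if "schedule" in obj else None,
        probs=np.asarray(obj["probs"], dtype=float) if "probs" in obj else None,
        transition=np.asarray(obj["transition"], dtype=float) if "transition" in obj else None,
        initial=np.asarray(obj["initial"], dtype=float) if "initial" in obj else None,
        seed=int(obj.get("seed", 0)),
    )


def load_environment(path) -> EnvironmentProcess:
    with open(path) as fh:
        return environment_from_dict(json.load(fh))


def save_environment(env: EnvironmentProcess, path) -> None:
    Path(path).write_text(json.dumps(environment_to_dict(env), indent=2) + "\n")


def trajectory_tsv(traj: Trajectory, landscape_label: str | None = None) -> str:
    """Render a trajectory as TSV, one row per recorded state."""
    n_coords = _state_vector(traj.states[0]).size
    header = f"# dynamic={traj.dynamic}"
    if landscape_label:
        header += f" landscape={landscape_label}"
    cols = ["t", "env_label", "mean_fitness"] + [f"x{i}" for i in range(n_coords)]
    lines = [header, "\t".join(cols)]
    for state, t in zip(traj.states, traj.state_steps):
        label = traj.env_labels[t - 1] if t >= 1 else "-"
        fit = repr(float(traj.mean_fitness[t - 1])) if t >= 1 else "nan"
        coords = "\t".join(repr(float(v)) for v in _state_vector(state))
        lines.append(f"{t}\t{label}\t{fit}\t{coords}")
    return "\n".join(lines) + "\n"


def save_trajectory(traj: Trajectory, path, landscape_label: str | None = None) -> None:
    Path(path).write_text(trajectory_tsv(traj, landscape_label))
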