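"""Multi-objective differential evolution with archive and spherical pruning.

The optimizer is a DE/rand/1/bin evolution over the bounded decision space
with three add-ons in the style of the spMODE algorithm family:

* an external archive of non-dominated solutions that survives generations,
* spherical pruning: the archived front, normalized to its ideal/nadir
  points, is divided into angular sectors and at most one solution (the one
  closest to the ideal point) is kept per occupied sector — enforcing an
  even spread along the trade-off curve,
* a pertinency bound mechanism: solutions whose objectives fall outside
  the designer's pertinency box are barred from the archive (they may
  linger in the population, preserving the search gradient).

Constraints are handled with Deb's feasibility rules: a feasible candidate
beats an infeasible one, infeasible candidates compare by constraint
violation, and feasible candidates compare by Pareto dominance.

A brute-force sampler (uniform Monte-Carlo or full grid, followed by the
same feasibility and dominance filters) provides the independent reference
front the evolutionary result is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from .errors import ConfigError
from .objectives import PertinencyBox

__all__ = [
    "EvalOutcome",
    "Individual",
    "MOOConfig",
    "ParetoApproximation",
    "OptimizationProblem",
    "dominates",
    "non_dominated_filter",
    "spherical_prune",
    "run",
    "brute_force_front",
    "hypervolume_2d",
    "generational_distance",
]


@dataclass(frozen=True)
class EvalOutcome:
    """What a problem returns for one decision vector."""

    J: tuple[float, float]
    P: float = 0.0
    violation: float = 0.0
    pertinent: bool = True
    feasible: bool = True


class OptimizationProblem(Protocol):
    """Bounded bi-objective problem interface consumed by the engine."""

    lower: np.ndarray
    upper: np.ndarray

    def __call__(self, theta: np.ndarray) -> EvalOutcome: ...


@dataclass(frozen=True)
class Individual:
    """One evaluated solution: decision vector plus objective-space image."""

    theta: np.ndarray
    J: tuple[float, float]
    P: float
    violation: float
    pertinent: bool
    feasible: bool

    @classmethod
    def from_outcome(cls, theta: np.ndarray, out: EvalOutcome) -> "Individual":
        return cls(np.asarray(theta, dtype=float), out.J, out.P,
                   out.violation, out.pertinent, out.feasible)


@dataclass(frozen=True)
class MOOConfig:
    """Optimizer settings.

    DE hyperparameters default to conventional values for this algorithm
    family (rand/1/bin, F=0.5, CR=0.9, population 50). ``sectors`` sets the
    spherical-pruning resolution and thereby caps the archive size; the
    default of 33 sectors yields an archive of roughly 33 well-spread
    solutions on a dense two-objective front — a practical number of
    candidate designs to carry into guideline extraction.
    """

    population: int = 50
    F: float = 0.5
    CR: float = 0.9
    max_evals: int = 15000
    sectors: int = 33
    box: Optional[PertinencyBox] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ConfigError("population must be >= 4 (DE/rand/1 needs 4 rows)")
        if not 0 < self.F <= 2:
            raise ConfigError("differential weight F must be in (0, 2]")
        if not 0 <= self.CR <= 1:
            raise ConfigError("crossover rate CR must be in [0, 1]")
        if self.max_evals <= self.population:
            raise ConfigError("max_evals must exceed the population size")
        if self.sectors < 1:
            raise ConfigError("sectors must be >= 1")


@dataclass
class ParetoApproximation:
    """Mutually non-dominated archive of (theta, J) pairs plus run metadata."""

    individuals: list[Individual]
    seed: Optional[int] = None
    evaluations: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.individuals)

    def front(self) -> np.ndarray:
        """Objective matrix, shape (n, 2)."""
        return np.array([ind.J for ind in self.individuals], dtype=float).reshape(-1, 2)

    def thetas(self) -> np.ndarray:
        """Decision matrix, shape (n, d)."""
        if not self.individuals:
            return np.empty((0, 0))
        return np.vstack([ind.theta for ind in self.individuals])

    def to_frame(self, names: Optional[Sequence[str]] = None):
        import pandas as pd

        front = self.front()
        thetas = self.thetas()
        d = thetas.shape[1] if len(self) else 0
        if names is None:
            names = [f"theta{j}" for j in range(d)]
        data = {
            "J1": front[:, 0] if len(self) else [],
            "J2": front[:, 1] if len(self) else [],
            "P": [ind.P for ind in self.individuals],
        }
        for j, name in enumerate(names):
            data[name] = thetas[:, j] if len(self) else []
        return pd.DataFrame(data)


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Pareto dominance (minimization): a is nowhere worse and somewhere better."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return bool(np.all(a <= b) and np.any(a < b))


def non_dominated_filter(inds: Sequence[Individual]) -> list[Individual]:
    """Keep the mutually non-dominated subset (first of exact duplicates)."""
    kept: list[Individual] = []
    J = [np.asarray(i.J, dtype=float) for i in inds]
    for i, ind in enumerate(inds):
        dominated = False
        for k, other in enumerate(inds):
            if k == i:
                continue
            if dominates(J[k], J[i]):
                dominated = True
                break
            if np.array_equal(J[k], J[i]) and k < i:
                dominated = True  # duplicate objective vector: keep first
                break
        if not dominated:
            kept.append(ind)
    return kept


def spherical_prune(archive: Sequence[Individual], sectors: int) -> list[Individual]:
    """At most one archive member per angular sector of the normalized front.

    Objectives are normalized to the archive's ideal/nadir box; each point's
    angle to the ideal point maps it to one of ``sectors`` equal sectors of
    the quarter circle, and within a sector the point with the smallest
    Euclidean norm to the ideal survives.
    """
    if not archive:
        return []
    if len(archive) == 1:
        return list(archive)
    J = np.array([ind.J for ind in archive], dtype=float)
    lo = J.min(axis=0)
    span = J.max(axis=0) - lo
    span[span <= 0] = 1.0
    Jn = (J - lo) / span
    angles = np.arctan2(Jn[:, 1], Jn[:, 0])  # in [0, pi/2]
    sector = np.minimum((angles / (np.pi / 2) * sectors).astype(int), sectors - 1)
    norms = np.linalg.norm(Jn, axis=1)
    best: dict[int, int] = {}
    for i, (s, r) in enumerate(zip(sector, norms)):
        if s not in best or r < norms[best[s]]:
            best[int(s)] = i
    return [archive[i] for i in sorted(best.values())]


def _update_archive(
    archive: list[Individual],
    candidates: Sequence[Individual],
    sectors: int,
) -> list[Individual]:
    admitted = [c for c in candidates if c.pertinent and c.feasible]
    if not admitted:
        return archive
    merged = non_dominated_filter(list(archive) + admitted)
    return spherical_prune(merged, sectors)


def _reflect(theta: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    out = theta.copy()
    below = out < lower
    out[below] = 2 * lower[below] - out[below]
    above = out > upper
    out[above] = 2 * upper[above] - out[above]
    return np.clip(out, lower, upper)  # guard against double overshoot


def _deb_better(trial: Individual, parent: Individual) -> bool:
    """Deb's rules; among mutually feasible, the trial survives unless the
    parent dominates it (the archive, not the population, holds elites)."""
    if trial.feasible and not parent.feasible:
        return True
    if parent.feasible and not trial.feasible:
        return False
    if not trial.feasible and not parent.feasible:
        return trial.violation <= parent.violation
    return not dominates(parent.J, trial.J)


def run(problem: OptimizationProblem, config: MOOConfig) -> ParetoApproximation:
    """Evolve a Pareto-front approximation under the evaluation budget.

    Deterministic given ``config.seed``. Returns the pruned external
    archive (all members pertinent, feasible and mutually non-dominated).
    """
    lower = np.asarray(problem.lower, dtype=float)
    upper = np.asarray(problem.upper, dtype=float)
    d = lower.size
    rng = np.random.default_rng(config.seed)
    npop = config.population

    def screen(out: EvalOutcome) -> EvalOutcome:
        if config.box is None:
            return out
        j1, j2 = out.J
        b = config.box
        pert = (
            np.isfinite(j1) and np.isfinite(j2)
            and b.j1[0] < j1 < b.j1[1] and b.j2[0] < j2 < b.j2[1]
        )
        feas = pert and b.p[0] < out.P < b.p[1]
        return EvalOutcome(out.J, out.P, out.violation, pert, feas)

    pop = lower + rng.random((npop, d)) * (upper - lower)
    inds = [Individual.from_outcome(t, screen(problem(t))) for t in pop]
    evals = npop
    archive = _update_archive([], inds, config.sectors)

    while evals + npop <= config.max_evals:
        trials = np.empty_like(pop)
        for i in range(npop):
            r1, r2, r3 = _distinct_indices(rng, npop, i)
            # archive members re-enter the evolution as mutation bases:
            # half the mutants build on stored non-dominated solutions,
            # which keeps the search anchored to the whole front instead
            # of wherever the population happens to drift.
            if archive and rng.random() < 0.5:
                base = archive[int(rng.integers(len(archive)))].theta
            else:
                base = pop[r1]
            mutant = base + config.F * (pop[r2] - pop[r3])
            mutant = _reflect(mutant, lower, upper)
            cross = rng.random(d) < config.CR
            cross[rng.integers(d)] = True
            trials[i] = np.where(cross, mutant, pop[i])
        trial_inds = [
            Individual.from_outcome(t, screen(problem(t))) for t in trials
        ]
        evals += npop
        for i in range(npop):
            if _deb_better(trial_inds[i], inds[i]):
                inds[i] = trial_inds[i]
                pop[i] = trials[i]
        archive = _update_archive(archive, trial_inds, config.sectors)

    return ParetoApproximation(
        individuals=archive,
        seed=config.seed,
        evaluations=evals,
        meta={
            "population": npop, "F": config.F, "CR": config.CR,
            "sectors": config.sectors, "max_evals": config.max_evals,
        },
    )


def _distinct_indices(rng: np.random.Generator, n: int, banned: int) -> tuple[int, int, int]:
    picks: list[int] = []
    while len(picks) < 3:
        c = int(rng.integers(n))
        if c != banned and c not in picks:
            picks.append(c)
    return picks[0], picks[1], picks[2]


def brute_force_front(
    problem: OptimizationProblem,
    sampler: str = "uniform",
    N: int = 1000,
    seed: int = 0,
) -> ParetoApproximation:
    """Sampled reference front: evaluate N points, keep the admissible
    non-dominated survivors.

    ``sampler="uniform"`` draws N uniform points; ``sampler="grid"`` lays a
    full factorial grid with round(N**(1/d)) levels per dimension.
    """
    lower = np.asarray(problem.lower, dtype=float)
    upper = np.asarray(problem.upper, dtype=float)
    d = lower.size
    if N < 1:
        raise ConfigError("N must be >= 1")
    if sampler == "uniform":
        rng = np.random.default_rng(seed)
        thetas = lower + rng.random((N, d)) * (upper - lower)
    elif sampler == "grid":
        per_dim = max(int(round(N ** (1.0 / d))), 2)
        axes = [np.linspace(lower[j], upper[j], per_dim) for j in range(d)]
        mesh = np.meshgrid(*axes, indexing="ij")
        thetas = np.stack([m.ravel() for m in mesh], axis=1)
    else:
        raise ConfigError(f"unknown sampler {sampler!r}")
    inds = [Individual.from_outcome(t, problem(t)) for t in thetas]
    admitted = [i for i in inds if i.pertinent and i.feasible]
    front = non_dominated_filter(admitted)
    return ParetoApproximation(
        individuals=front, seed=seed, evaluations=len(inds),
        meta={"sampler": sampler, "N": int(N)},
    )


def hypervolume_2d(front: np.ndarray, reference: Sequence[float]) -> float:
    """Dominated hypervolume of a 2-objective front w.r.t. a reference point."""
    front = np.asarray(front, dtype=float).reshape(-1, 2)
    ref = np.asarray(reference, dtype=float)
    pts = front[np.all(front <= ref, axis=1)]
    if pts.size == 0:
        return 0.0
    pts = pts[np.argsort(pts[:, 0])]
    hv = 0.0
    prev_j2 = ref[1]
    for j1, j2 in pts:
        if j2 < prev_j2:
            hv += (ref[0] - j1) * (prev_j2 - j2)
            prev_j2 = j2
    return hv


def generational_distance(
    front: np.ndarray, true_front: Callable[[float], float] | np.ndarray
) -> float:
    """Mean distance from each front point to the closest reference point.

    ``true_front`` is either a dense reference matrix or a callable mapping
    J1 to the analytic J2 on the true front (sampled densely internally).
    """
    front = np.asarray(front, dtype=float).reshape(-1, 2)
    if callable(true_front):
        j1 = np.linspace(front[:, 0].min(), front[:, 0].max(), 2001)
        ref = np.stack([j1, np.array([true_front(v) for v in j1])], axis=1)
    else:
        ref = np.asarray(true_front, dtype=float).reshape(-1, 2)
    dists = np.sqrt(
        ((front[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    ).min(axis=1)
    return float(dists.mean())
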