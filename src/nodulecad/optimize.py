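"""Metaheuristic maximization of the Otsu objective over threshold sets.

Three population searches over integer threshold vectors share one contract:
they maximize sigma_B^2 (via :class:`~nodulecad.otsu.OtsuObjective`), are
fully reproducible under a seed, record a trace (best fitness per iteration,
total objective evaluations) and return the best candidate found.

* Cuckoo search: each nest proposes a new solution by a Levy-flight
  perturbation, the proposal replaces a randomly chosen nest if fitter, and
  each iteration a fraction Pa of the worst nests is abandoned and rebuilt by
  fresh Levy flights; the best nest is never abandoned (elitism).
* PSO: standard global-best particle swarm with inertia, cognitive and
  social coefficients, velocities clamped to [-vmax, vmax].
* GA: generational genetic algorithm with tournament selection, one-point
  crossover, per-gene uniform mutation, elitism of one.

Searches run in continuous space; candidates are repaired (round, clamp to
[0, L-2], sort, deduplicate) to integer threshold vectors before every
evaluation, preserving the discrete gray-level semantics of thresholding.

Levy steps use the Mantegna algorithm: with tail index gamma in (1, 3] and
beta = gamma - 1, step = u / |v|^(1/beta) with u ~ N(0, sigma_u^2),
v ~ N(0, 1), which yields P(|step| > s) ~ s^(-beta), i.e. a density tail
~ |s|^(-gamma).  At gamma = 3 exactly the Mantegna scale degenerates
(sin(pi*beta/2) = 0) and a plain Gaussian step is used instead.

An optional evaluation budget makes cross-optimizer comparisons fair: when
``max_evaluations`` is set, the search stops as soon as the budget is spent
(a batch is truncated mid-iteration if needed), so traces from different
optimizers report identical evaluation counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .otsu import OtsuObjective, ThresholdSet

__all__ = [
    "CuckooConfig",
    "PSOConfig",
    "GAConfig",
    "CandidateSolution",
    "OptimizerTrace",
    "levy_step",
    "cuckoo_search",
    "pso_search",
    "ga_search",
    "search",
]


@dataclass(frozen=True)
class CuckooConfig:
    """Cuckoo-search hyperparameters.

    n host nests, abandonment probability Pa, max iterations M, step size
    alpha (gray levels), Levy tail index gamma in (1, 3], k thresholds.
    The defaults follow common cuckoo-search practice with M = 200
    iterations.
    """

    n: int = 25
    pa: float = 0.25
    max_iter: int = 200
    alpha: float = 1.0
    gamma: float = 1.5
    k: int = 1
    seed: int = 0
    max_evaluations: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one nest")
        if not 0.0 <= self.pa <= 1.0:
            raise ValueError("Pa must be in [0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 1.0 < self.gamma <= 3.0:
            raise ValueError("gamma must be in (1, 3]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class PSOConfig:
    """Global-best PSO hyperparameters over the same threshold space."""

    n: int = 25
    max_iter: int = 200
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    vmax: float = 40.0
    k: int = 1
    seed: int = 0
    max_evaluations: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1 or self.max_iter < 1 or self.k < 1:
            raise ValueError("n, max_iter and k must be positive")


@dataclass(frozen=True)
class GAConfig:
    """Generational GA hyperparameters (tournament 3, elitism 1)."""

    n: int = 25
    max_iter: int = 200
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    tournament: int = 3
    k: int = 1
    seed: int = 0
    max_evaluations: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2 or self.max_iter < 1 or self.k < 1:
            raise ValueError("n >= 2, max_iter and k must be positive")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass(frozen=True)
class CandidateSolution:
    """One nest/particle/individual: a threshold set and its fitness."""

    thresholds: ThresholdSet
    fitness: float


@dataclass
class OptimizerTrace:
    """Progress record: per-iteration best (non-decreasing) and eval count."""

    best_fitness_per_iteration: list[float] = field(default_factory=list)
    evaluations: int = 0
    best: CandidateSolution | None = None


def levy_step(
    gamma: float,
    scale: float,
    rng: np.random.Generator,
    size=None,
) -> np.ndarray | float:
    """Heavy-tailed Levy displacement(s) via Mantegna's algorithm.

    ``gamma`` is the tail index of the step-length density (1 < gamma <= 3);
    ``scale`` multiplies the raw step.  Deterministic for a given ``rng``
    state.
    """
    if not 1.0 < gamma <= 3.0:
        raise ValueError("gamma must be in (1, 3]")
    beta = gamma - 1.0
    if beta >= 2.0:  # Mantegna scale degenerates; Gaussian limit
        return scale * rng.standard_normal(size)
    sigma_u = (
        math.gamma(1 + beta)
        * math.sin(math.pi * beta / 2)
        / (math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    ) ** (1.0 / beta)
    u = rng.normal(0.0, sigma_u, size)
    v = rng.standard_normal(size)
    return scale * u / np.abs(v) ** (1.0 / beta)


def _repair(X: np.ndarray, k: int, levels: int) -> np.ndarray:
    """Round/clamp/sort real vectors into valid strictly-increasing sets."""
    V = np.clip(np.rint(X), 0, levels - 2).astype(np.int64)
    V.sort(axis=-1)
    # forward pass: enforce strict increase; backward pass: respect the cap
    for i in range(1, k):
        V[..., i] = np.maximum(V[..., i], V[..., i - 1] + 1)
    for i in range(k - 1, -1, -1):
        V[..., i] = np.minimum(V[..., i], levels - 2 - (k - 1 - i))
    for i in range(1, k):
        V[..., i] = np.maximum(V[..., i], V[..., i - 1] + 1)
    return V


class _Budget:
    """Counts objective evaluations; truncates batches at the budget."""

    def __init__(self, objective: OtsuObjective, limit: int | None):
        self.objective = objective
        self.limit = limit
        self.used = 0

    @property
    def exhausted(self) -> bool:
        return self.limit is not None and self.used >= self.limit

    def evaluate(self, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate as many rows as the budget allows.

        Returns (fitness, evaluated_row_mask)."""
        n = len(T)
        if self.limit is None:
            take = n
        else:
            take = min(n, self.limit - self.used)
        mask = np.zeros(n, dtype=bool)
        mask[:take] = True
        f = np.full(n, -np.inf)
        if take:
            f[:take] = self.objective.batch(T[:take])
        self.used += take
        return f, mask


def _iterations(max_iter: int, budget: _Budget):
    """Iteration source: the budget governs when one is set, else max_iter."""
    if budget.limit is not None:
        return iter(int, 1)  # endless; loop exits when the budget is spent
    return range(max_iter)


def _init_population(n: int, k: int, levels: int, rng: np.random.Generator):
    X = rng.uniform(0, levels - 2, size=(n, k))
    return _repair(X, k, levels)


def _finish(trace: OptimizerTrace, nests, fits, levels) -> CandidateSolution:
    i = int(np.argmax(fits))
    best = CandidateSolution(
        ThresholdSet(tuple(int(v) for v in nests[i]), levels), float(fits[i])
    )
    trace.best = best
    return best


def cuckoo_search(
    objective: OtsuObjective, config: CuckooConfig
) -> tuple[CandidateSolution, OptimizerTrace]:
    """Cuckoo search with Levy flights over threshold sets."""
    rng = np.random.default_rng(config.seed)
    L = objective.levels
    k = config.k
    budget = _Budget(objective, config.max_evaluations)
    trace = OptimizerTrace()

    nests = _init_population(config.n, k, L, rng)
    fits, _ = budget.evaluate(nests)

    for _ in _iterations(config.max_iter, budget):
        if budget.exhausted:
            break
        # Levy-flight proposals: one cuckoo egg per nest
        steps = levy_step(config.gamma, config.alpha, rng, size=(config.n, k))
        proposals = _repair(nests + steps, k, L)
        f_prop, mask = budget.evaluate(proposals)
        hosts = rng.integers(0, config.n, size=config.n)
        for i in range(config.n):
            if not mask[i]:
                break
            j = hosts[i]
            if f_prop[i] > fits[j]:
                nests[j] = proposals[i]
                fits[j] = f_prop[i]
        # abandon the worst Pa fraction (never the current best) and rebuild
        n_aband = int(round(config.pa * config.n))
        if n_aband and not budget.exhausted:
            order = np.argsort(fits)  # ascending: worst first
            worst = [int(i) for i in order if i != int(np.argmax(fits))][:n_aband]
            steps = levy_step(config.gamma, config.alpha, rng, size=(len(worst), k))
            rebuilt = _repair(nests[worst] + steps, k, L)
            f_new, mask = budget.evaluate(rebuilt)
            for idx, i in enumerate(worst):
                if not mask[idx]:
                    break
                nests[i] = rebuilt[idx]
                fits[i] = f_new[idx]
        trace.best_fitness_per_iteration.append(float(fits.max()))
    trace.evaluations = budget.used
    return _finish(trace, nests, fits, L), trace


def pso_search(
    objective: OtsuObjective, config: PSOConfig
) -> tuple[CandidateSolution, OptimizerTrace]:
    """Global-best PSO over threshold sets (positions repaired per step)."""
    rng = np.random.default_rng(config.seed)
    L = objective.levels
    k = config.k
    budget = _Budget(objective, config.max_evaluations)
    trace = OptimizerTrace()

    X = rng.uniform(0, L - 2, size=(config.n, k))
    V = rng.uniform(-config.vmax, config.vmax, size=(config.n, k)) * 0.1
    P = X.copy()  # personal bests (continuous positions)
    f_p, _ = budget.evaluate(_repair(X, k, L))
    g = int(np.argmax(f_p))
    gbest_x = P[g].copy()
    gbest_f = float(f_p[g])

    for _ in _iterations(config.max_iter, budget):
        if budget.exhausted:
            break
        r1 = rng.random((config.n, k))
        r2 = rng.random((config.n, k))
        V = (
            config.inertia * V
            + config.cognitive * r1 * (P - X)
            + config.social * r2 * (gbest_x[None, :] - X)
        )
        np.clip(V, -config.vmax, config.vmax, out=V)
        X = np.clip(X + V, 0, L - 2)
        f, mask = budget.evaluate(_repair(X, k, L))
        improved = mask & (f > f_p)
        P[improved] = X[improved]
        f_p[improved] = f[improved]
        g = int(np.argmax(f_p))
        if f_p[g] > gbest_f:
            gbest_f = float(f_p[g])
            gbest_x = P[g].copy()
        trace.best_fitness_per_iteration.append(gbest_f)
    trace.evaluations = budget.used
    best_t = _repair(gbest_x[None, :], k, L)[0]
    best = CandidateSolution(
        ThresholdSet(tuple(int(v) for v in best_t), L), gbest_f
    )
    trace.best = best
    return best, trace


def ga_search(
    objective: OtsuObjective, config: GAConfig
) -> tuple[CandidateSolution, OptimizerTrace]:
    """Generational GA with tournament selection and one-point crossover."""
    rng = np.random.default_rng(config.seed)
    L = objective.levels
    k = config.k
    budget = _Budget(objective, config.max_evaluations)
    trace = OptimizerTrace()

    pop = _init_population(config.n, k, L, rng)
    fits, _ = budget.evaluate(pop)

    def tournament() -> int:
        idx = rng.integers(0, config.n, size=config.tournament)
        return int(idx[np.argmax(fits[idx])])

    for _ in _iterations(config.max_iter, budget):
        if budget.exhausted:
            break
        elite = int(np.argmax(fits))
        children = np.empty_like(pop)
        children[0] = pop[elite]  # elitism of one
        i = 1
        while i < config.n:
            a, b = pop[tournament()].copy(), pop[tournament()].copy()
            if k > 1 and rng.random() < config.crossover_rate:
                cut = int(rng.integers(1, k))
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            for child in (a, b):
                if i >= config.n:
                    break
                mut = rng.random(k) < config.mutation_rate
                if mut.any():
                    child = child.astype(float)
                    child[mut] = rng.uniform(0, L - 2, size=int(mut.sum()))
                children[i] = _repair(child.astype(float), k, L)
                i += 1
        f_children, mask = budget.evaluate(children[1:])
        new_fits = np.concatenate(([fits[elite]], np.where(mask, f_children, -np.inf)))
        keep = mask.sum() + 1
        pop = np.vstack([children[:1], children[1:][mask]])
        fits = new_fits[: keep]
        if len(pop) < config.n:  # budget ran out mid-generation
            trace.best_fitness_per_iteration.append(float(fits.max()))
            break
        trace.best_fitness_per_iteration.append(float(fits.max()))
    trace.evaluations = budget.used
    return _finish(trace, pop, fits, L), trace


_SEARCHERS = {
    "cso": (cuckoo_search, CuckooConfig),
    "pso": (pso_search, PSOConfig),
    "ga": (ga_search, GAConfig),
}


def search(
    objective: OtsuObjective, optimizer: str = "cso", **kwargs
) -> tuple[CandidateSolution, OptimizerTrace]:
    """Run a named optimizer (``cso``, ``pso`` or ``ga``) with config kwargs."""
    try:
        fn, cfg_cls = _SEARCHERS[optimizer]
    except KeyError:
        raise ValueError(f"unknown optimizer {optimizer!r}; use cso|pso|ga") from None
    return fn(objective, cfg_cls(**kwargs))


def trace_to_csv(trace: OptimizerTrace, path) -> None:
    """Dump best-fitness-per-iteration for inspection."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "best_fitness"])
        for i, f in enumerate(trace.best_fitness_per_iteration):
            w.writerow([i, f])
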