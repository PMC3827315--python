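"""NSGA-II with task fitness and behavioral novelty as objectives.

The single-objective problem of maximizing task fitness is lifted to two
objectives to mitigate premature convergence: (1) the episodic fitness on
the evolutionary training set and (2) behavioral novelty, the mean
Euclidean distance from an individual's behavior descriptor to its k
nearest neighbors in the union of the current population and an archive.
Variation is mutation-only; survivor selection is mu+lambda over the
combined parent/offspring pool by (Pareto rank, crowding distance), which
makes the best-so-far fitness non-decreasing.  At the end the novelty
objective is discarded: the result is the individual with the best fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .encodings.base import DevelopmentError
from .task import AssociationSet, TaskConfig, evaluate_fitness


@dataclass
class Individual:
    genotype: object
    fitness: Optional[float] = None
    descriptor: Optional[np.ndarray] = None
    set_success: Optional[np.ndarray] = None
    novelty: float = 0.0
    rank: Optional[int] = None
    crowding: float = 0.0
    error: bool = False


@dataclass
class NoveltyParams:
    """k: neighborhood size; one uniformly chosen offspring descriptor is
    appended to the (unbounded) archive each generation."""

    k: int = 15

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class EvolutionConfig:
    population_size: int = 400
    max_generations: int = 4000
    stop_on_perfect: bool = True
    novelty: NoveltyParams = field(default_factory=NoveltyParams)
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population size must be even and >= 4")


def fast_nondominated_sort(points: Sequence[Tuple[float, float]]) -> List[List[int]]:
    """Pareto fronts under maximization of both objectives.

    Returns lists of indices; front 0 is the non-dominated set.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    dominates = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (pts[i] >= pts[j]).all() and (pts[i] > pts[j]).any():
                dominates[i].append(j)
    for i in range(n):
        for j in dominates[i]:
            dom_count[j] += 1
    fronts = []
    current = [i for i in range(n) if dom_count[i] == 0]
    while current:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominates[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = nxt
    return fronts


def crowding_distance(points: Sequence[Tuple[float, float]]) -> np.ndarray:
    """Standard NSGA-II crowding distance within one front."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        raise ValueError("front must be non-empty")
    dist = np.zeros(n)
    for m in range(pts.shape[1]):
        order = np.argsort(pts[:, m], kind="stable")
        dist[order[0]] = dist[order[-1]] = np.inf
        span = pts[order[-1], m] - pts[order[0], m]
        if span <= 0:
            continue
        for k in range(1, n - 1):
            dist[order[k]] += (pts[order[k + 1], m] - pts[order[k - 1], m]) / span
    return dist


def novelty_scores(
    descriptors: np.ndarray, archive: Optional[np.ndarray], k: int
) -> np.ndarray:
    """Mean Euclidean distance to the k nearest neighbors in
    population + archive, self excluded; if fewer than k others exist the
    mean is over the whole pool."""
    desc = np.atleast_2d(np.asarray(descriptors, dtype=float))
    pool = desc if archive is None or len(archive) == 0 else np.vstack([desc, archive])
    if pool.shape[1] != desc.shape[1]:
        raise ValueError("descriptor length mismatch")
    d = cdist(desc, pool)
    n = desc.shape[0]
    scores = np.zeros(n)
    for i in range(n):
        row = np.delete(d[i], i)  # self sits at pool index i
        if row.size == 0:
            scores[i] = 0.0
            continue
        kk = min(k, row.size)
        scores[i] = float(np.sort(row)[:kk].mean())
    return scores


def _eval_rng(seed: int, generation: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, generation, index]))


def _evaluate(
    ind: Individual,
    encoding,
    training_set: Sequence[AssociationSet],
    task_config: TaskConfig,
    rng: np.random.Generator,
    desc_len: int,
) -> None:
    """Fitness + descriptor; development failures get minimal fitness."""
    try:
        net = encoding.develop(ind.genotype)
        res = evaluate_fitness(net, training_set, task_config, rng)
        ind.fitness = res.fitness
        ind.descriptor = res.descriptor
        ind.set_success = res.set_success
    except DevelopmentError:
        ind.fitness = 0.0
        ind.descriptor = np.zeros(desc_len)
        ind.set_success = np.zeros(len(training_set), dtype=bool)
        ind.error = True


def _assign_fronts(pop: List[Individual]) -> None:
    pts = [(ind.fitness, ind.novelty) for ind in pop]
    fronts = fast_nondominated_sort(pts)
    for rank, front in enumerate(fronts):
        dists = crowding_distance([pts[i] for i in front])
        for i, d in zip(front, dists):
            pop[i].rank = rank
            pop[i].crowding = float(d)


def _tournament(pop: List[Individual], rng: np.random.Generator) -> Individual:
    a, b = (pop[int(i)] for i in rng.integers(0, len(pop), size=2))
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    if a.crowding != b.crowding:
        return a if a.crowding > b.crowding else b
    return a if rng.random() < 0.5 else b


@dataclass
class EvolveResult:
    best: Individual
    history: List[dict]
    population: List[Individual]
    archive: List[np.ndarray]
    generations: int
    converged: bool


def evolve(
    training_set: Sequence[AssociationSet],
    encoding,
    config: EvolutionConfig,
    task_config: Optional[TaskConfig] = None,
    progress: Optional[Callable[[dict], None]] = None,
) -> EvolveResult:
    """Run the mutation-only NSGA-II loop.

    Each individual is evaluated exactly once, with an RNG derived from
    (run seed, generation, index), so runs are reproducible and re-runs
    with the same seed byte-identical.  Terminates at perfect fitness on
    the training set (if ``stop_on_perfect``) or at the generation cap.
    """
    task_config = task_config if task_config is not None else TaskConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE0]))
    desc_len = 4 * task_config.n_actions * len(training_set)
    n = config.population_size

    pop = [Individual(encoding.random_init(rng)) for _ in range(n)]
    for i, ind in enumerate(pop):
        _evaluate(ind, encoding, training_set, task_config, _eval_rng(config.seed, 0, i), desc_len)

    archive: List[np.ndarray] = []
    history: List[dict] = []
    converged = False
    gen = 0

    def refresh(pool: List[Individual]) -> None:
        desc = np.array([ind.descriptor for ind in pool])
        arch = np.array(archive) if archive else None
        scores = novelty_scores(desc, arch, config.novelty.k)
        for ind, s in zip(pool, scores):
            ind.novelty = float(s)
        _assign_fronts(pool)

    refresh(pop)

    for gen in range(1, config.max_generations + 1):
        best = max(ind.fitness for ind in pop)
        record = {
            "generation": gen - 1,
            "best_fitness": best,
            "mean_fitness": float(np.mean([ind.fitness for ind in pop])),
            "archive_size": len(archive),
        }
        history.append(record)
        if progress is not None:
            progress(record)
        if config.stop_on_perfect and best >= 1.0:
            converged = True
            gen -= 1
            break

        offspring = []
        for i in range(n):
            parent = _tournament(pop, rng)
            child = Individual(encoding.mutate(parent.genotype, rng))
            _evaluate(
                child, encoding, training_set, task_config,
                _eval_rng(config.seed, gen, i), desc_len,
            )
            offspring.append(child)
        archive.append(offspring[int(rng.integers(0, n))].descriptor.copy())

        combined = pop + offspring
        refresh(combined)
        order = sorted(
            range(len(combined)),
            key=lambda i: (combined[i].rank, -combined[i].crowding),
        )
        pop = [combined[i] for i in order[:n]]
    else:
        gen = config.max_generations

    best_ind = max(pop, key=lambda ind: ind.fitness)
    if config.stop_on_perfect and best_ind.fitness >= 1.0:
        converged = True
    return EvolveResult(
        best=best_ind,
        history=history,
        population=pop,
        archive=archive,
        generations=gen,
        converged=converged,
    )
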