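"""Genetic-algorithm search over fixed-size gene subsets.

A "chromosome" is a set of distinct gene indices of fixed length (default
20); its fitness is the leave-one-out KNN training accuracy of that gene
subset.  The search stops as soon as the best chromosome classifies at
least ``stop_fitness`` (default 90%) of the training samples correctly, or
after ``max_generations``.  A single run returns one near-optimal subset;
the surrounding ensemble machinery repeats runs to map the space of
equally discriminative subsets.

Operator choices (tournament selection, uniform union-repair crossover,
per-position replacement mutation, small elitism) are standard for
fixed-size subset encodings; every guarantee the package tests —
closure, elitist monotonicity, determinism — is operator-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .knn import training_fitness

__all__ = ["GAConfig", "GARunResult", "mutate", "crossover", "evolve"]


@dataclass(frozen=True)
class GAConfig:
    """Search settings.  Defaults follow the GA/KNN lineage:

    20-gene chromosomes, a population of 300, at most 300 generations,
    k = 5 neighbors, and a 90% training-accuracy stopping rule.
    """

    chromosome_length: int = 20
    population_size: int = 300
    max_generations: int = 300
    stop_fitness: float = 0.90
    k_neighbors: int = 5
    mutation_rate: float = 0.05
    crossover_rate: float = 0.9
    elitism_count: int = 2
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chromosome_length < 1:
            raise ValueError("chromosome_length must be at least 1")
        if self.population_size < 1:
            raise ValueError("population_size must be at least 1")
        if self.max_generations < 0:
            raise ValueError("max_generations must be non-negative")
        if not 0 < self.stop_fitness <= 1:
            raise ValueError("stop_fitness must be in (0, 1]")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be at least 1")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be at least 1")


@dataclass(frozen=True)
class GARunResult:
    """Outcome of one GA run.

    ``best_subset`` is canonicalized (sorted indices).  ``stopped_early``
    is true exactly when the stopping fitness was reached before the
    generation budget ran out.  ``fitness_history[g]`` is the best-ever
    fitness after evaluating generation g (index 0 = initial population);
    it is non-decreasing because of elitism.
    """

    best_subset: np.ndarray
    best_fitness: float
    generations_used: int
    stopped_early: bool
    fitness_history: tuple[float, ...] = field(default=(), repr=False)


def mutate(
    subset: np.ndarray, n_genes: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Replace each position independently with probability ``rate``.

    A mutated position gets a uniform draw from the genes not currently in
    the subset, so the result is always a distinct-gene subset of the same
    size.  When every gene is already in the subset there is no legal
    replacement and the subset is returned unchanged.
    """
    subset = np.asarray(subset, dtype=int)
    out = subset.copy()
    flip = rng.random(out.size) < rate
    for pos in np.flatnonzero(flip):
        outside = np.setdiff1d(np.arange(n_genes), out, assume_unique=False)
        if outside.size == 0:
            break
        out[pos] = rng.choice(outside)
    return out


def crossover(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform crossover with duplicate repair.

    Positionwise, each child takes one parent's gene and its sibling the
    other's; a duplicate introduced this way is repaired by a uniform draw
    from the parental gene pool (union of both parents) not yet in the
    child.  Children therefore have the parents' length, distinct genes,
    and genes only from the parental pool.
    """
    a = np.asarray(parent_a, dtype=int)
    b = np.asarray(parent_b, dtype=int)
    if a.size != b.size:
        raise ValueError("parents must have equal length")
    pool = np.union1d(a, b)
    swap = rng.random(a.size) < 0.5
    child_a = np.where(swap, b, a)
    child_b = np.where(swap, a, b)

    def _repair(child: np.ndarray) -> np.ndarray:
        seen: set[int] = set()
        dup_pos = []
        for i, g in enumerate(child.tolist()):
            if g in seen:
                dup_pos.append(i)
            else:
                seen.add(g)
        for i in dup_pos:
            candidates = np.setdiff1d(pool, child[np.arange(child.size) != i])
            # |pool| >= length, so a candidate always exists
            child[i] = rng.choice(candidates)
            # re-check: the chosen candidate is outside the rest of the child
        return child

    return _repair(child_a), _repair(child_b)


def _random_subset(n_genes: int, length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(n_genes, size=length, replace=False)


def evolve(
    train_values: np.ndarray,
    train_labels: list[str] | np.ndarray,
    config: GAConfig,
) -> GARunResult:
    """Run one GA search and return the best-ever gene subset.

    The loop is: evaluate population -> check stopping rule -> tournament
    selection -> crossover -> mutation -> elitist replacement.  Fitnesses
    are cached by the sorted gene tuple, since subsets recur.  Identical
    data + config (including its seed) reproduce the result exactly.
    """
    train_values = np.asarray(train_values, dtype=float)
    n_genes = train_values.shape[0]
    if n_genes < config.chromosome_length:
        raise ValueError(
            f"chromosome_length {config.chromosome_length} exceeds "
            f"{n_genes} available genes"
        )
    rng = np.random.default_rng(config.seed)
    labels = np.asarray(train_labels)

    cache: dict[tuple[int, ...], float] = {}

    def fitness(subset: np.ndarray) -> float:
        key = tuple(sorted(subset.tolist()))
        if key not in cache:
            cache[key] = training_fitness(
                train_values, labels, subset, config.k_neighbors
            )
        return cache[key]

    population = [
        _random_subset(n_genes, config.chromosome_length, rng)
        for _ in range(config.population_size)
    ]
    scores = np.array([fitness(ind) for ind in population])

    best_idx = int(scores.argmax())
    best_subset = population[best_idx].copy()
    best_fitness = float(scores[best_idx])
    history = [best_fitness]

    generations_used = 0
    stopped_early = False
    for gen in range(1, config.max_generations + 1):
        if best_fitness >= config.stop_fitness:
            stopped_early = True
            break
        # elitism: carry the current best individuals over unchanged
        elite_order = np.argsort(-scores, kind="stable")[: config.elitism_count]
        next_pop = [population[i].copy() for i in elite_order]

        def select() -> np.ndarray:
            contenders = rng.integers(0, config.population_size, config.tournament_size)
            winner = contenders[np.argmax(scores[contenders])]
            return population[winner]

        while len(next_pop) < config.population_size:
            pa, pb = select(), select()
            if rng.random() < config.crossover_rate:
                ca, cb = crossover(pa, pb, rng)
            else:
                ca, cb = pa.copy(), pb.copy()
            ca = mutate(ca, n_genes, config.mutation_rate, rng)
            cb = mutate(cb, n_genes, config.mutation_rate, rng)
            next_pop.append(ca)
            if len(next_pop) < config.population_size:
                next_pop.append(cb)

        population = next_pop
        scores = np.array([fitness(ind) for ind in population])
        generations_used = gen
        gen_best = int(scores.argmax())
        if scores[gen_best] > best_fitness:
            best_fitness = float(scores[gen_best])
            best_subset = population[gen_best].copy()
        history.append(best_fitness)

    if best_fitness >= config.stop_fitness and generations_used < config.max_generations:
        stopped_early = True

    return GARunResult(
        best_subset=np.sort(best_subset),
        best_fitness=best_fitness,
        generations_used=generations_used,
        stopped_early=stopped_early,
        fitness_history=tuple(history),
    )
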