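"""Generational grammatical-evolution loop for predictor expressions.

Classic operator set: tournament selection, variable-length single-point
crossover, integer-flip mutation, and elitism, minimizing the glucose-
specific MSE of a candidate's 120-min forecasts over one training segment.
Default parameters: population 50, 2000 generations, crossover 0.90,
mutation 0.005, elitism 2, tournament size 2, wrap budget 2.

Genotypes that fail to map (or map to a malformed phenotype) receive a
worst-marker fitness of ``inf`` and still take part in selection, keeping
the population size fixed without a repair loop. Fitness values are cached
by codon string — mapping and evaluation dominate the runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expressions import (PredictorExpression, PhenotypeError, parse_phenotype,
                          evaluate_series, PREDICTION_HORIZON_SAMPLES)
from .grammar import Grammar, Genotype, map_genotype, random_genotype
from .metrics import PenParams, PairedSeries, gmse

__all__ = [
    "GEConfig",
    "Individual",
    "EvolutionLog",
    "TrainingSegment",
    "decode",
    "segment_fitness",
    "tournament_select",
    "single_point_crossover",
    "integer_flip_mutation",
    "evolve",
]

WORST_FITNESS = float("inf")


@dataclass(frozen=True)
class GEConfig:
    """Evolution parameters; defaults are the full-scale run settings."""

    population_size: int = 50
    generations: int = 2000
    crossover_prob: float = 0.90
    mutation_prob: float = 0.005
    elitism_count: int = 2
    tournament_size: int = 2
    max_wraps: int = 2
    min_init_len: int = 15
    max_init_len: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.population_size <= 0 or self.generations < 0:
            raise ValueError("population must be positive, generations nonnegative")
        if not (0 <= self.elitism_count < self.population_size):
            raise ValueError("elitism_count must be below population_size")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be positive")


@dataclass
class Individual:
    """A genotype with its (lower-is-better) fitness; inf marks invalid mappings."""

    genotype: Genotype
    fitness: float = WORST_FITNESS

    @property
    def valid(self) -> bool:
        return np.isfinite(self.fitness)


@dataclass
class EvolutionLog:
    """Per-generation progress of one evolution run."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    invalid_fraction: list[float] = field(default_factory=list)
    best_phenotype: list[str] = field(default_factory=list)

    def record(self, population: list[Individual], best: Individual,
               phenotype: str) -> None:
        fits = np.array([ind.fitness for ind in population])
        finite = fits[np.isfinite(fits)]
        self.best_fitness.append(best.fitness)
        self.mean_fitness.append(float(finite.mean()) if finite.size else WORST_FITNESS)
        self.invalid_fraction.append(float(np.mean(~np.isfinite(fits))))
        self.best_phenotype.append(phenotype)


@dataclass
class TrainingSegment:
    """Aligned training data for one day segment on the 5-min CGM grid.

    ``g``, ``ra``, ``iob`` are full-history arrays; ``n_indices`` are the
    sample indices at which predictions are made, and ``targets`` the CGM
    references one horizon later (``g[n + 24]``). Off-segment timestamps are
    simply absent from ``n_indices`` — excluding them from the loss sum is
    equivalent to the convention of holding the model output constant there.
    """

    g: np.ndarray
    ra: np.ndarray
    iob: np.ndarray
    n_indices: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.n_indices = np.asarray(self.n_indices, dtype=int)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.n_indices.size != self.targets.size:
            raise ValueError("one target per prediction index required")
        if self.n_indices.size < 1:
            raise ValueError("training segment holds no (history, target) pairs")


def decode(genotype: Genotype, grammar: Grammar,
           max_wraps: int = 2) -> PredictorExpression | None:
    """Map and parse a genotype; ``None`` when the result is not a valid predictor."""
    result = map_genotype(genotype, grammar, max_wraps=max_wraps)
    if result.phenotype is None:
        return None
    try:
        return parse_phenotype(result.phenotype)
    except PhenotypeError:
        return None


def segment_fitness(expr: PredictorExpression, segment: TrainingSegment,
                    pen_params: PenParams) -> float:
    """gMSE of the expression's forecasts over the segment's timestamps."""
    preds = evaluate_series(expr, segment.g, segment.ra, segment.iob,
                            segment.n_indices)
    preds = np.clip(preds, 1.0, 1e6)  # metric domain requires positive forecasts
    value = gmse(PairedSeries(segment.targets, preds), pen_params)
    return value if np.isfinite(value) else WORST_FITNESS


def tournament_select(population: list[Individual], rng: np.random.Generator,
                      tournament_size: int = 2) -> Individual:
    """Best of ``tournament_size`` individuals drawn uniformly with replacement."""
    if not population:
        raise ValueError("population is empty")
    picks = rng.integers(0, len(population), size=tournament_size)
    return min((population[i] for i in picks), key=lambda ind: ind.fitness)


def single_point_crossover(parent_a: Genotype, parent_b: Genotype,
                           rng: np.random.Generator,
                           crossover_prob: float = 1.0,
                           max_cut_a: int | None = None,
                           max_cut_b: int | None = None) -> tuple[Genotype, Genotype]:
    """Variable-length single-point crossover.

    With probability ``1 - crossover_prob`` the parents are copied unchanged.
    Otherwise an independent cut point is drawn in each parent (uniform over
    [0, length]) and the tails are exchanged; cut pairs producing an empty
    child are redrawn, which preserves total codon count.

    ``max_cut_a``/``max_cut_b`` optionally bound the cut to a parent's
    expressed (codon-consuming) region — effective crossover, which keeps
    the operator from silently swapping unread tail material.
    """
    if rng.random() >= crossover_prob:
        return parent_a, parent_b
    a, b = parent_a.codons, parent_b.codons
    hi_a = len(a) if max_cut_a is None else min(len(a), max_cut_a)
    hi_b = len(b) if max_cut_b is None else min(len(b), max_cut_b)
    for _ in range(64):
        i = int(rng.integers(0, hi_a + 1))
        j = int(rng.integers(0, hi_b + 1))
        child_a = a[:i] + b[j:]
        child_b = b[:j] + a[i:]
        if child_a and child_b:
            return Genotype(child_a), Genotype(child_b)
    return parent_a, parent_b  # degenerate lengths; keep parents


def integer_flip_mutation(genotype: Genotype, rng: np.random.Generator,
                          mutation_prob: float = 0.005) -> Genotype:
    """Each codon independently redrawn uniformly from [0, 255] with the given probability."""
    codons = np.array(genotype.codons, dtype=int)
    flip = rng.random(codons.size) < mutation_prob
    if flip.any():
        codons[flip] = rng.integers(0, 256, size=int(flip.sum()))
    return Genotype(tuple(int(c) for c in codons))


def evolve(segment: TrainingSegment, grammar: Grammar,
           config: GEConfig = GEConfig(),
           pen_params: PenParams = PenParams()) -> tuple[Individual, EvolutionLog]:
    """Run the generational GE loop on one training segment.

    Returns the best-ever individual and the per-generation log. The run is
    a pure function of (segment, grammar, config): a fixed ``rng_seed``
    reproduces it bitwise.
    """
    rng = np.random.default_rng(config.rng_seed)
    cache: dict[tuple, tuple[float, int]] = {}  # codons -> (fitness, used length)

    def evaluate_genotype(genotype: Genotype) -> tuple[float, int]:
        key = genotype.codons
        if key not in cache:
            mapped = map_genotype(genotype, grammar, config.max_wraps)
            used = min(len(genotype), mapped.codons_consumed) or len(genotype)
            if mapped.phenotype is None:
                cache[key] = (WORST_FITNESS, used)
            else:
                try:
                    expr = parse_phenotype(mapped.phenotype)
                    cache[key] = (segment_fitness(expr, segment, pen_params), used)
                except PhenotypeError:
                    cache[key] = (WORST_FITNESS, used)
        return cache[key]

    def fitness_of(genotype: Genotype) -> float:
        return evaluate_genotype(genotype)[0]

    population = [Individual(random_genotype(rng, config.min_init_len,
                                             config.max_init_len))
                  for _ in range(config.population_size)]
    for ind in population:
        ind.fitness = fitness_of(ind.genotype)

    best = min(population, key=lambda ind: ind.fitness)
    best = Individual(best.genotype, best.fitness)
    log = EvolutionLog()
    log.record(population, best, _phenotype_of(best, grammar, config))

    for _ in range(config.generations):
        elites = sorted(population, key=lambda ind: ind.fitness)[:config.elitism_count]
        offspring: list[Individual] = [Individual(e.genotype, e.fitness) for e in elites]
        while len(offspring) < config.population_size:
            pa = tournament_select(population, rng, config.tournament_size)
            pb = tournament_select(population, rng, config.tournament_size)
            ca, cb = single_point_crossover(
                pa.genotype, pb.genotype, rng, config.crossover_prob,
                max_cut_a=evaluate_genotype(pa.genotype)[1],
                max_cut_b=evaluate_genotype(pb.genotype)[1])
            for child in (ca, cb):
                child = integer_flip_mutation(child, rng, config.mutation_prob)
                if len(offspring) < config.population_size:
                    offspring.append(Individual(child, fitness_of(child)))
        population = offspring
        gen_best = min(population, key=lambda ind: ind.fitness)
        if gen_best.fitness < best.fitness:
            best = Individual(gen_best.genotype, gen_best.fitness)
        log.record(population, best, _phenotype_of(best, grammar, config))

    return best, log


def _phenotype_of(ind: Individual, grammar: Grammar, config: GEConfig) -> str:
    expr = decode(ind.genotype, grammar, config.max_wraps)
    return expr.to_text() if expr is not None else "<invalid>"
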