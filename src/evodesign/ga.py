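"""Fitness evaluation, selection, crossover, mutation and generation turnover.

The interactive loop evaluates each tested condition with a weighted sum of
per-generation min-max-normalised objective responses:

    score = sum_j w_j * t_j,
    t_j = (x_j - min_j) / (max_j - min_j)          for maximised objectives,
    t_j = 1 - (x_j - min_j) / (max_j - min_j)      for minimised objectives,

with the extremes taken over the *current generation only*, so every score
lies in [0, 1] when the weights sum to one.  Replicate measurements are
reduced to a median after a single missing value (out of three) is repaired
with the mean of the remaining replicates.

Selection composes truncation with roulette wheel: the better-scoring
``selection_fraction`` of the population forms the mating pool, inside which
parents are drawn with probability proportional to score.  Crossover is
single-point (suffix exchange); mutation flips exactly one uniformly chosen
bit with the configured per-chromosome probability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design_space import Chromosome, DesignSpace
from .errors import DataError, StateError

__all__ = [
    "GAParams",
    "MeasurementTable",
    "FitnessResult",
    "GenerationRecord",
    "aggregate_replicates",
    "evaluate_fitness",
    "select_parent_pairs",
    "crossover",
    "mutate",
    "next_generation",
    "random_population",
]

logger = logging.getLogger(__name__)

MISSING = float("nan")


@dataclass(frozen=True)
class GAParams:
    """Tunable parameters of the evolutionary loop.

    ``selection_fraction`` is the share of the population admitted to the
    mating pool (0.5 by default: the better-performing half).  The crossover
    rate applies per offspring pair, the mutation rate per offspring
    chromosome.  The library default mutation rate is 0.01; medium
    optimisation studies typically raise it to ~0.1.  ``elitism`` copies the
    best k individuals unchanged into the next generation (off by default).
    """

    population_size: int
    selection_fraction: float = 0.5
    crossover_rate: float = 0.9
    mutation_rate: float = 0.01
    elitism: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 < self.selection_fraction <= 1:
            raise ValueError("selection_fraction must be in (0, 1]")
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must be in [0, 1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")


@dataclass
class MeasurementTable:
    """Raw replicate responses for one generation.

    ``rows`` maps are keyed ``(chromosome_id, replicate_index)`` ->
    {objective: value}; NaN marks a missing single measurement.
    """

    generation_index: int
    rows: list[tuple[str, int, dict[str, float]]]

    @classmethod
    def from_dataframe(cls, generation_index: int, df: pd.DataFrame,
                       objectives: Sequence[str]) -> "MeasurementTable":
        missing_cols = [c for c in ("condition_id", "replicate") if c not in df.columns]
        if missing_cols:
            raise DataError(f"results table lacks required columns {missing_cols}")
        absent = [o for o in objectives if o not in df.columns]
        if absent:
            raise DataError(f"results table lacks objective columns {absent}")
        rows = []
        for _, r in df.iterrows():
            rows.append(
                (
                    str(r["condition_id"]),
                    int(r["replicate"]),
                    {o: float(r[o]) if pd.notna(r[o]) else MISSING for o in objectives},
                )
            )
        return cls(generation_index, rows)


@dataclass
class FitnessResult:
    """Per-chromosome normalised objective terms and total weighted score."""

    terms: dict[str, dict[str, float]]  # id -> objective -> [0,1] term
    totals: dict[str, float]  # id -> weighted score

    def ranked_ids(self) -> list[str]:
        """Ids sorted by score descending, ties broken by id order (stable)."""
        return [
            cid
            for cid, _ in sorted(
                self.totals.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]


@dataclass
class GenerationRecord:
    """One round of the loop: population, optional measurements and fitness."""

    generation_index: int
    population: list[Chromosome]
    measurements: Optional[MeasurementTable] = None
    aggregated: Optional[dict[tuple[str, str], float]] = None
    fitness: Optional[FitnessResult] = None
    seed: Optional[int] = None


def aggregate_replicates(
    table: MeasurementTable,
) -> dict[tuple[str, str], float]:
    """Median response per (chromosome, objective) after single-miss repair.

    A single missing replicate is replaced by the arithmetic mean of the
    remaining replicates before the median is taken; two or more missing
    replicates in one cell are not repairable and raise :class:`DataError`.
    """
    cells: dict[tuple[str, str], list[float]] = {}
    for cid, _rep, values in table.rows:
        for obj, v in values.items():
            cells.setdefault((cid, obj), []).append(v)
    out: dict[tuple[str, str], float] = {}
    for (cid, obj), vals in cells.items():
        present = [v for v in vals if not math.isnan(v)]
        n_missing = len(vals) - len(present)
        if not present:
            raise DataError(f"no usable replicates for ({cid!r}, {obj!r})")
        if n_missing >= 2:
            raise DataError(
                f"{n_missing} missing replicates for ({cid!r}, {obj!r}); "
                "only a single missing value per cell is repairable"
            )
        if n_missing == 1:
            present = present + [sum(present) / len(present)]
        out[(cid, obj)] = float(np.median(present))
    return out


def evaluate_fitness(
    space: DesignSpace,
    aggregated: Mapping[tuple[str, str], float],
    ids: Sequence[str],
) -> FitnessResult:
    """Weighted min-max-normalised score of each chromosome in a generation.

    Extremes are taken over the supplied generation only.  A degenerate
    objective (max == min within the generation) contributes the neutral
    term 0.5 for every individual, with a logged warning.
    """
    ids = list(ids)
    terms: dict[str, dict[str, float]] = {cid: {} for cid in ids}
    totals: dict[str, float] = {cid: 0.0 for cid in ids}
    for obj in space.objectives:
        try:
            values = {cid: aggregated[(cid, obj.name)] for cid in ids}
        except KeyError as e:
            raise DataError(f"aggregated results missing cell {e.args[0]!r}") from e
        lo, hi = min(values.values()), max(values.values())
        for cid in ids:
            if hi == lo:
                t = 0.5
            else:
                t = (values[cid] - lo) / (hi - lo)
                if obj.direction == "minimize":
                    t = 1.0 - t
            terms[cid][obj.name] = t
            totals[cid] += obj.weight * t
        if hi == lo:
            logger.warning(
                "objective %r is degenerate in this generation "
                "(all values %.6g); neutral term 0.5 used", obj.name, lo,
            )
    return FitnessResult(terms, totals)


def _mating_pool(fitness: FitnessResult, params: GAParams) -> list[str]:
    ranked = fitness.ranked_ids()
    n_pool = math.ceil(params.selection_fraction * len(ranked))
    if n_pool < 2:
        logger.warning("mating pool of %d expanded to the top 2 individuals", n_pool)
        n_pool = 2
    return ranked[:n_pool]


def _roulette(pool: list[str], scores: np.ndarray, rng: np.random.Generator) -> int:
    total = scores.sum()
    if total <= 0:
        return int(rng.integers(len(pool)))
    return int(rng.choice(len(pool), p=scores / total))


def select_parent_pairs(
    fitness: FitnessResult, params: GAParams, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """ceil(N/2) parent pairs by truncation + roulette-wheel selection.

    The top ``selection_fraction`` of the population (by score, ties broken
    by id) forms the pool; within it each parent is drawn with probability
    proportional to its score (uniformly if all pool scores are zero).  The
    two parents of a pair are distinct individuals.
    """
    pool = _mating_pool(fitness, params)
    scores = np.array([fitness.totals[cid] for cid in pool], dtype=float)
    n_pairs = math.ceil(params.population_size / 2)
    pairs: list[tuple[str, str]] = []
    for _ in range(n_pairs):
        i = _roulette(pool, scores, rng)
        j = i
        for _attempt in range(100):
            j = _roulette(pool, scores, rng)
            if j != i:
                break
        if j == i:
            # only one pool member carries weight: pick the mate uniformly
            others = [k for k in range(len(pool)) if k != i]
            j = int(rng.choice(others))
        pairs.append((pool[i], pool[j]))
    return pairs


def crossover(
    parent1: Chromosome,
    parent2: Chromosome,
    rate: float,
    rng: np.random.Generator,
    ids: tuple[str, str] = ("", ""),
) -> tuple[Chromosome, Chromosome]:
    """Single-point crossover: with probability ``rate`` exchange suffixes.

    The cut point is uniform on 1..L-1; otherwise the parents are returned
    as (fresh) copies.  Children never alias the parent objects.
    """
    if len(parent1) != len(parent2):
        raise ValueError(
            f"parent lengths differ: {len(parent1)} vs {len(parent2)}"
        )
    L = len(parent1)
    if L < 2:
        raise ValueError("chromosomes must have length >= 2 for crossover")
    b1, b2 = parent1.bits, parent2.bits
    if rng.random() < rate:
        cut = int(rng.integers(1, L))
        c1 = b1[:cut] + b2[cut:]
        c2 = b2[:cut] + b1[cut:]
    else:
        c1, c2 = tuple(b1), tuple(b2)
    return Chromosome(c1, ids[0]), Chromosome(c2, ids[1])


def mutate(
    child: Chromosome, rate: float, rng: np.random.Generator
) -> Chromosome:
    """With probability ``rate`` flip exactly one uniformly chosen bit."""
    if rng.random() < rate:
        pos = int(rng.integers(len(child)))
        bits = list(child.bits)
        bits[pos] ^= 1
        return Chromosome(tuple(bits), child.id)
    return Chromosome(tuple(child.bits), child.id)


def next_generation(
    record: GenerationRecord,
    params: GAParams,
    rng: np.random.Generator,
) -> GenerationRecord:
    """Produce the next population via select -> crossover -> mutate.

    Population size and chromosome length are preserved; offspring receive
    fresh ids ``G<gen>C<k>``.  Duplicates among offspring are permitted.
    """
    if record.fitness is None:
        raise StateError("ingest results first: current generation has no fitness")
    by_id = {c.id: c for c in record.population}
    gen = record.generation_index + 1
    offspring: list[Chromosome] = []
    if params.elitism:
        for cid in record.fitness.ranked_ids()[: params.elitism]:
            offspring.append(Chromosome(by_id[cid].bits, ""))
    pairs = select_parent_pairs(record.fitness, params, rng)
    for p1_id, p2_id in pairs:
        c1, c2 = crossover(by_id[p1_id], by_id[p2_id], params.crossover_rate, rng)
        offspring.append(mutate(c1, params.mutation_rate, rng))
        if len(offspring) < params.population_size:
            offspring.append(mutate(c2, params.mutation_rate, rng))
        if len(offspring) >= params.population_size:
            break
    offspring = offspring[: params.population_size]
    offspring = [
        Chromosome(c.bits, f"G{gen}C{k + 1:02d}") for k, c in enumerate(offspring)
    ]
    return GenerationRecord(generation_index=gen, population=offspring)


def random_population(
    space: DesignSpace,
    params: GAParams,
    rng: np.random.Generator,
) -> GenerationRecord:
    """Generation 1: independent fair-coin bits for every chromosome."""
    L = space.chromosome_length
    pop = [
        Chromosome(
            tuple(int(b) for b in rng.integers(0, 2, size=L)), f"G1C{k + 1:02d}"
        )
        for k in range(params.population_size)
    ]
    return GenerationRecord(generation_index=1, population=pop)
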