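"""In-memory driver: run the GA loop against a synthetic oracle.

This is the programmatic counterpart of the interactive propose / measure /
ingest / step cycle: the oracle stands in for the wet lab, so whole
multi-generation studies run in milliseconds.  Used by the examples, the
`simulate` CLI command and the recovery tests.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design_space import DesignSpace, decode_chromosome, population_size_rule
from .ga import (
    GAParams,
    GenerationRecord,
    MeasurementTable,
    aggregate_replicates,
    evaluate_fitness,
    next_generation,
    random_population,
)
from .oracle import SyntheticOracle

__all__ = ["derived_seed", "design_table", "run_ga", "history_dataset"]


def derived_seed(session_seed: int, generation: int) -> int:
    """Deterministic per-generation seed below 2**31, derived from the session seed."""
    ss = np.random.SeedSequence([int(session_seed), int(generation)])
    return int(ss.generate_state(1)[0] % (2**31))


def design_table(space: DesignSpace, record: GenerationRecord) -> pd.DataFrame:
    """Decoded physical conditions of a generation, one row per chromosome."""
    rows = []
    for chrom in record.population:
        row: dict[str, object] = {
            "condition_id": chrom.id,
            "generation": record.generation_index,
        }
        row.update(decode_chromosome(space, chrom))
        rows.append(row)
    return pd.DataFrame(rows)


def ingest_measurements(
    space: DesignSpace, record: GenerationRecord, results: pd.DataFrame
) -> None:
    """Attach measurements to a generation record and compute fitness in place."""
    table = MeasurementTable.from_dataframe(
        record.generation_index, results, space.objective_names
    )
    record.measurements = table
    record.aggregated = aggregate_replicates(table)
    record.fitness = evaluate_fitness(
        space, record.aggregated, [c.id for c in record.population]
    )


def run_ga(
    oracle: SyntheticOracle,
    generations: int,
    seed: int = 0,
    params: Optional[GAParams] = None,
) -> list[GenerationRecord]:
    """Drive ``generations`` rounds of propose -> measure -> score -> evolve.

    Every round of measurements in the returned history has fitness
    computed, including the final generation.  All randomness (population
    initialisation, selection, variation, measurement noise) derives from
    ``seed``, so runs replay identically.
    """
    space = oracle.space
    if params is None:
        n = len(space.factors)
        pop = population_size_rule(n) if n >= 2 else 4
        params = GAParams(population_size=pop, mutation_rate=0.1, seed=seed)
    history: list[GenerationRecord] = []
    rng = np.random.default_rng(derived_seed(seed, 1))
    record = random_population(space, params, rng)
    record.seed = derived_seed(seed, 1)
    for g in range(1, generations + 1):
        design = design_table(space, record)
        results = oracle.respond(
            design, rng=np.random.default_rng(derived_seed(seed, 100000 + g))
        )
        ingest_measurements(space, record, results)
        history.append(record)
        if g < generations:
            step_seed = derived_seed(seed, g + 1)
            record = next_generation(
                record, params, np.random.default_rng(step_seed)
            )
            record.seed = step_seed
    return history


def history_dataset(
    space: DesignSpace,
    history: Sequence[GenerationRecord],
) -> pd.DataFrame:
    """Flatten a history into a modelling table: factors + aggregated responses.

    One row per tested chromosome with its decoded factor levels and the
    replicate-aggregated (median) value of every objective — the dataset on
    which symbolic-regression surrogates are trained.
    """
    rows = []
    for rec in history:
        if rec.aggregated is None:
            continue
        for chrom in rec.population:
            row: dict[str, object] = {
                "condition_id": chrom.id,
                "generation": rec.generation_index,
            }
            row.update(decode_chromosome(space, chrom))
            for obj in space.objective_names:
                row[obj] = rec.aggregated[(chrom.id, obj)]
            rows.append(row)
    return pd.DataFrame(rows)
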