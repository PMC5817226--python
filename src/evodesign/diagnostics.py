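"""Convergence metrics and population profiling.

Two complementary readouts guide the decision to stop the experimental loop
and to read off optimal factor levels:

* **Score trajectories** — per generation, the mean score of the whole
  population, the mean of its better-performing fraction, and the best
  individual; a one-sided Welch t-test between the better fractions of
  adjacent generations quantifies whether scores are still improving.
  The relative standard deviation (RSD = sample SD / mean) of the better
  fraction signals contraction of the search onto an optimal sub-space.

* **Population profiling** — per factor and generation, the absolute
  frequency with which each encoded level is occupied; the *occupancy
  footprint* is the percent share of each level within the better half of
  the final generation, from which optimal settings are chosen.

Termination is advisory: the functions report metrics, the user decides.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design_space import DesignSpace, chromosome_level_indices
from .errors import StateError
from .ga import GenerationRecord

__all__ = [
    "score_trajectories",
    "relative_standard_deviation",
    "population_profile",
    "occupancy_footprint",
    "improvement_test",
    "better_fraction_scores",
]

logger = logging.getLogger(__name__)


def _scores_for(record: GenerationRecord, objective: Optional[str]) -> dict[str, float]:
    if record.fitness is None:
        raise StateError(
            f"generation {record.generation_index} has no fitness computed"
        )
    if objective is None:
        return dict(record.fitness.totals)
    return {cid: t[objective] for cid, t in record.fitness.terms.items()}


def better_fraction_scores(
    record: GenerationRecord,
    fraction: float = 0.5,
    objective: Optional[str] = None,
) -> list[float]:
    """Scores of the top ``ceil(fraction * N)`` individuals (by total score)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores = _scores_for(record, objective)
    ranked = record.fitness.ranked_ids()
    top = ranked[: math.ceil(fraction * len(ranked))]
    return [scores[cid] for cid in top]


def score_trajectories(
    history: Sequence[GenerationRecord],
    fraction: float = 0.5,
    objective: Optional[str] = None,
) -> pd.DataFrame:
    """Mean-all / mean-better-fraction / best score per generation.

    ``objective=None`` uses the total weighted score; naming an objective
    uses its normalised per-generation term instead.  Membership of the
    better fraction is always decided by the total score, mirroring how the
    better-performing half of a generation is defined experimentally.
    """
    rows = []
    for rec in history:
        scores = _scores_for(rec, objective)
        vals = np.array(list(scores.values()))
        top_vals = np.array(better_fraction_scores(rec, fraction, objective))
        rows.append(
            {
                "generation": rec.generation_index,
                "mean_all": vals.mean(),
                "mean_better_fraction": top_vals.mean(),
                "best": vals.max(),
            }
        )
    return pd.DataFrame(rows)


def relative_standard_deviation(scores: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("RSD needs at least 2 scores")
    mean = x.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero-mean scores")
    return float(x.std(ddof=1) / mean)


def population_profile(
    history: Sequence[GenerationRecord],
    space: DesignSpace,
    include_zero: bool = False,
) -> pd.DataFrame:
    """Absolute level-occupancy frequency per factor per generation.

    Returns a tidy frame (factor, generation, level_index, level_value,
    frequency).  By default only levels that appeared at least once are
    listed; ``include_zero`` reports the full level grid.
    """
    counts: dict[tuple[str, int, int], int] = {}
    for rec in history:
        for chrom in rec.population:
            for fname, k in chromosome_level_indices(space, chrom).items():
                key = (fname, rec.generation_index, k)
                counts[key] = counts.get(key, 0) + 1
    rows = []
    gens = sorted({rec.generation_index for rec in history})
    for f in space.factors:
        for g in gens:
            for k in range(f.n_levels):
                freq = counts.get((f.name, g, k), 0)
                if freq or include_zero:
                    rows.append(
                        {
                            "factor": f.name,
                            "generation": g,
                            "level_index": k,
                            "level_value": f.level_value(k),
                            "frequency": freq,
                        }
                    )
    return pd.DataFrame(rows)


def occupancy_footprint(
    last_generation: GenerationRecord,
    space: DesignSpace,
    fraction: float = 0.5,
) -> pd.DataFrame:
    """Percent occupancy of each level within the better-performing fraction.

    Restricted to the top ``ceil(fraction * N)`` individuals of the supplied
    (normally final) generation; per factor the percentages sum to 100.
    """
    if last_generation.fitness is None:
        raise StateError("occupancy footprint requires fitness on the generation")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ranked = last_generation.fitness.ranked_ids()
    top_ids = set(ranked[: math.ceil(fraction * len(ranked))])
    subset = [c for c in last_generation.population if c.id in top_ids]
    counts: dict[tuple[str, int], int] = {}
    for chrom in subset:
        for fname, k in chromosome_level_indices(space, chrom).items():
            counts[(fname, k)] = counts.get((fname, k), 0) + 1
    rows = []
    for f in space.factors:
        for k in range(f.n_levels):
            c = counts.get((f.name, k), 0)
            if c:
                rows.append(
                    {
                        "factor": f.name,
                        "level_index": k,
                        "level_value": f.level_value(k),
                        "percent": 100.0 * c / len(subset),
                    }
                )
    return pd.DataFrame(rows)


def improvement_test(
    scores_prev: Sequence[float], scores_next: Sequence[float]
) -> float:
    """One-sided Welch t-test p-value for mean(next) > mean(prev).

    Intended for the better-performing fractions of adjacent generations;
    practice is to keep iterating while p < 0.05 signals clear improvement
    and to consider stopping once p > 0.1.  If both groups have zero
    variance the statistic is undefined: equal means report p = 1.0 (with a
    warning), otherwise the continuity limit 0.0 / 1.0 by sign of the shift.
    """
    a = np.asarray(scores_prev, dtype=float)
    b = np.asarray(scores_next, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("improvement test needs >= 2 scores per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            logger.warning("degenerate improvement test: all scores identical")
            return 1.0
        return 0.0 if b.mean() > a.mean() else 1.0
    res = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
    return float(res.pvalue)
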