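import numpy as np
import pytest

from evodesign import (
    Chromosome,
    DesignSpace,
    FactorSpec,
    FitnessResult,
    GenerationRecord,
    ObjectiveSpec,
)


@pytest.fixture
def two_factor_space():
    return DesignSpace(
        factors=[
            FactorSpec("a", 0.0, 7.0, bits=3),
            FactorSpec("b", 0.0, 7.0, bits=3),
        ],
        objectives=[ObjectiveSpec("y", "maximize", 1.0)],
    )


@pytest.fixture
def case_study_space():
    """Nine 5-bit factors, four equally weighted objectives."""
    names = [
        "ammonium", "potassium", "magnesium", "iron", "calcium",
        "glycerol", "methanol", "sorbitol",
    ]
    factors = [FactorSpec(n, 0.0, 10.0, bits=5, units="g/l") for n in names]
    factors.append(FactorSpec("ph", 2.6, 7.0, bits=5, units="pH"))
    objectives = [
        ObjectiveSpec("od_pre", "maximize", 0.25),
        ObjectiveSpec("od_gain", "minimize", 0.25),
        ObjectiveSpec("enzyme_activity", "maximize", 0.25),
        ObjectiveSpec("specific_productivity", "maximize", 0.25),
    ]
    return DesignSpace(factors, objectives)


def make_scored_generation(scores, gen=1, length=6):
    """GenerationRecord with given total scores and dummy chromosomes."""
    rng = np.random.default_rng(0)
    pop = [
        Chromosome(tuple(int(b) for b in rng.integers(0, 2, length)), f"G{gen}C{i+1:02d}")
        for i in range(len(scores))
    ]
    totals = {c.id: float(s) for c, s in zip(pop, scores)}
    terms = {c.id: {"y": float(s)} for c, s in zip(pop, scores)}
    return GenerationRecord(
        generation_index=gen,
        population=pop,
        fitness=FitnessResult(terms=terms, totals=totals),
    )
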