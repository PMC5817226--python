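"""Fitness normalisation, selection, variation operators and turnover."""

import numpy as np
import pytest
from scipy import stats

from evodesign import (
    Chromosome,
    DataError,
    DesignSpace,
    FactorSpec,
    GAParams,
    MeasurementTable,
    ObjectiveSpec,
    StateError,
    aggregate_replicates,
    crossover,
    evaluate_fitness,
    mutate,
    next_generation,
    random_population,
    select_parent_pairs,
)
from evodesign.ga import FitnessResult

NAN = float("nan")


def table(cells):
    """cells: {(cid, obj): [replicate values]} -> MeasurementTable."""
    rows = []
    n_rep = max(len(v) for v in cells.values())
    by_cid = {}
    for (cid, obj), vals in cells.items():
        by_cid.setdefault(cid, {})[obj] = vals
    for cid, objs in by_cid.items():
        for r in range(n_rep):
            rows.append((cid, r + 1, {o: v[r] for o, v in objs.items()}))
    return MeasurementTable(1, rows)


class TestAggregateReplicates:
    def test_median_of_three(self):
        agg = aggregate_replicates(table({("c1", "y"): [2.0, 4.0, 6.0]}))
        assert agg[("c1", "y")] == 4.0

    def test_single_missing_repaired_with_mean(self):
        agg = aggregate_replicates(table({("c1", "y"): [2.0, NAN, 6.0]}))
        assert agg[("c1", "y")] == 4.0

    def test_median_robust_to_outlier(self):
        agg = aggregate_replicates(table({("c1", "y"): [1.0, 10.0, 100.0]}))
        assert agg[("c1", "y")] == 10.0

    def test_two_missing_rejected_with_cell(self):
        with pytest.raises(DataError, match="c1.*'y'"):
            aggregate_replicates(table({("c1", "y"): [NAN, NAN, 6.0]}))


class TestEvaluateFitness:
    @pytest.fixture
    def space(self):
        return DesignSpace(
            [FactorSpec("x", 0, 1)],
            [
                ObjectiveSpec("up", "maximize", 0.5),
                ObjectiveSpec("down", "minimize", 0.5),
            ],
        )

    def test_extreme_individuals_score_one_and_zero(self, space):
        agg = {
            ("best", "up"): 10.0, ("best", "down"): 1.0,
            ("worst", "up"): 2.0, ("worst", "down"): 5.0,
            ("mid", "up"): 6.0, ("mid", "down"): 3.0,
        }
        fr = evaluate_fitness(space, agg, ["best", "worst", "mid"])
        assert fr.totals["best"] == pytest.approx(1.0)
        assert fr.totals["worst"] == pytest.approx(0.0)
        assert 0.0 < fr.totals["mid"] < 1.0

    def test_single_objective_linear_spread(self):
        space = DesignSpace([FactorSpec("x", 0, 1)], [ObjectiveSpec("y")])
        agg = {("a", "y"): 10.0, ("b", "y"): 15.0, ("c", "y"): 20.0}
        fr = evaluate_fitness(space, agg, ["a", "b", "c"])
        assert [fr.totals[i] for i in "abc"] == pytest.approx([0.0, 0.5, 1.0])

    def test_degenerate_objective_neutral(self, space):
        agg = {
            ("a", "up"): 3.0, ("a", "down"): 1.0,
            ("b", "up"): 3.0, ("b", "down"): 2.0,
        }
        fr = evaluate_fitness(space, agg, ["a", "b"])
        assert fr.terms["a"]["up"] == 0.5
        assert fr.terms["b"]["up"] == 0.5
        # the informative minimise objective still separates them
        assert fr.totals["a"] > fr.totals["b"]

    def test_scores_bounded(self, space):
        rng = np.random.default_rng(3)
        ids = [f"c{i}" for i in range(10)]
        agg = {(i, o): rng.uniform(0, 50) for i in ids for o in ("up", "down")}
        fr = evaluate_fitness(space, agg, ids)
        assert all(0.0 <= fr.totals[i] <= 1.0 for i in ids)
        assert all(0.0 <= t <= 1.0 for ts in fr.terms.values() for t in ts.values())


def fitness_of(scores):
    totals = {f"c{i}": s for i, s in enumerate(scores)}
    return FitnessResult(terms={k: {} for k in totals}, totals=totals)


class TestSelection:
    def test_roulette_proportional_to_score(self):
        """Pool scores 3:1 -> first pool member drawn ~75% of the time."""
        fr = fitness_of([3.0, 1.0])
        params = GAParams(population_size=2, selection_fraction=1.0, seed=0)
        rng = np.random.default_rng(42)
        counts = {"c0": 0, "c1": 0}
        n = 10_000
        for _ in range(n):
            pairs = select_parent_pairs(fr, params, rng)
            counts[pairs[0][0]] += 1
        expected = [0.75 * n, 0.25 * n]
        chi2 = sum(
            (obs - exp) ** 2 / exp for obs, exp in zip(counts.values(), expected)
        )
        assert stats.chi2.sf(chi2, df=1) > 0.01

    def test_uniform_when_scores_equal(self):
        fr = fitness_of([0.0, 0.0, 0.0, 0.0])
        params = GAParams(population_size=4, selection_fraction=1.0, seed=0)
        rng = np.random.default_rng(7)
        counts = np.zeros(4)
        n = 8000
        for _ in range(n):
            first = select_parent_pairs(fr, params, rng)[0][0]
            counts[int(first[1:])] += 1
        chi2 = ((counts - n / 4) ** 2 / (n / 4)).sum()
        assert stats.chi2.sf(chi2, df=3) > 0.01

    def test_pool_and_pair_counts_case_study(self):
        fr = fitness_of(np.linspace(0, 1, 16))
        params = GAParams(population_size=16, selection_fraction=0.5, seed=0)
        pairs = select_parent_pairs(fr, params, np.random.default_rng(0))
        assert len(pairs) == 8
        pool_ids = {f"c{i}" for i in range(8, 16)}  # top half by score
        for p1, p2 in pairs:
            assert p1 != p2
            assert p1 in pool_ids and p2 in pool_ids


class TestCrossover:
    def test_suffix_swap(self):
        p1 = Chromosome((0,) * 6, "p1")
        p2 = Chromosome((1,) * 6, "p2")
        rng = np.random.default_rng(0)
        c1, c2 = crossover(p1, p2, rate=1.0, rng=rng)
        # per-position multiset conserved: one 0 and one 1 at every position
        for i in range(6):
            assert sorted((c1.bits[i], c2.bits[i])) == [0, 1]
        assert c1.bits != p1.bits or c2.bits != p2.bits

    def test_rate_zero_returns_copies(self):
        p1 = Chromosome((0, 1, 0, 1), "p1")
        p2 = Chromosome((1, 1, 0, 0), "p2")
        c1, c2 = crossover(p1, p2, 0.0, np.random.default_rng(0))
        assert c1.bits == p1.bits and c2.bits == p2.bits
        assert c1 is not p1 and c2 is not p2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            crossover(
                Chromosome((0, 1), "a"), Chromosome((0, 1, 1), "b"),
                0.9, np.random.default_rng(0),
            )


class TestMutate:
    def test_forced_flip_changes_exactly_one_bit(self):
        child = Chromosome((0, 1, 0, 1, 1), "c")
        rng = np.random.default_rng(1)
        for _ in range(50):
            out = mutate(child, 1.0, rng)
            assert sum(a != b for a, b in zip(out.bits, child.bits)) == 1

    def test_rate_zero_identity(self):
        child = Chromosome((0, 1, 0), "c")
        assert mutate(child, 0.0, np.random.default_rng(0)).bits == child.bits

    def test_mutation_frequency_matches_rate(self):
        child = Chromosome((0,) * 10, "c")
        rng = np.random.default_rng(5)
        n = 10_000
        mutated = sum(mutate(child, 0.1, rng).bits != child.bits for _ in range(n))
        lo, hi = stats.binom.interval(0.99, n, 0.1)
        assert lo <= mutated <= hi


class TestTurnover:
    @pytest.fixture
    def scored_record(self, two_factor_space):
        params = GAParams(population_size=6, seed=0)
        rec = random_population(two_factor_space, params, np.random.default_rng(0))
        totals = {c.id: i / 5 for i, c in enumerate(rec.population)}
        rec.fitness = FitnessResult({k: {} for k in totals}, totals)
        return rec, params

    def test_same_seed_reproduces_offspring(self, scored_record):
        rec, params = scored_record
        g1 = next_generation(rec, params, np.random.default_rng(99))
        g2 = next_generation(rec, params, np.random.default_rng(99))
        assert [c.bits for c in g1.population] == [c.bits for c in g2.population]

    def test_population_size_and_length_preserved(self, two_factor_space):
        params = GAParams(population_size=16, seed=0)
        rec = random_population(two_factor_space, params, np.random.default_rng(1))
        totals = {c.id: i / 15 for i, c in enumerate(rec.population)}
        rec.fitness = FitnessResult({k: {} for k in totals}, totals)
        nxt = next_generation(rec, params, np.random.default_rng(2))
        assert len(nxt.population) == 16
        assert all(len(c) == 6 for c in nxt.population)
        assert nxt.generation_index == rec.generation_index + 1

    def test_zero_rates_copy_selected_parents(self, scored_record):
        rec, _ = scored_record
        params = GAParams(
            population_size=6, crossover_rate=0.0, mutation_rate=0.0, seed=0
        )
        nxt = next_generation(rec, params, np.random.default_rng(3))
        parent_bits = {c.bits for c in rec.population}
        assert all(c.bits in parent_bits for c in nxt.population)

    def test_requires_fitness(self, two_factor_space):
        params = GAParams(population_size=6, seed=0)
        rec = random_population(two_factor_space, params, np.random.default_rng(0))
        with pytest.raises(StateError, match="ingest"):
            next_generation(rec, params, np.random.default_rng(0))


class TestRandomPopulation:
    def test_fair_coin_bits(self, two_factor_space):
        params = GAParams(population_size=200, seed=0)
        rec = random_population(two_factor_space, params, np.random.default_rng(11))
        ones = sum(sum(c.bits) for c in rec.population)
        n = 200 * 6
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= ones <= hi

    def test_case_study_shape(self, case_study_space):
        params = GAParams(population_size=16, seed=0)
        rec = random_population(case_study_space, params, np.random.default_rng(0))
        assert len(rec.population) == 16
        assert all(len(c) == 45 for c in rec.population)
        assert rec.generation_index == 1

    def test_different_seeds_differ(self, case_study_space):
        params = GAParams(population_size=16, seed=0)
        r1 = random_population(case_study_space, params, np.random.default_rng(0))
        r2 = random_population(case_study_space, params, np.random.default_rng(1))
        assert [c.bits for c in r1.population] != [c.bits for c in r2.population]
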