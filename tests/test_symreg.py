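"""Expression trees, least-squares gene weighting and the GP search."""

import numpy as np
import pandas as pd
import pytest

from evodesign import (
    DataError,
    SRParams,
    evaluate_tree,
    evolve_models,
    fit_batch,
    fit_mlr,
    fit_weights,
)
from evodesign.symreg import _pdiv, tree_depth, tree_factors


def x(name):
    return ("x", name)


def c(v):
    return ("c", float(v))


class TestEvaluateTree:
    def test_arithmetic(self):
        tree = ("mul", ("add", x("x1"), x("x2")), x("x3"))
        assert evaluate_tree(tree, {"x1": 1, "x2": 2, "x3": 3}) == 9.0

    def test_protected_division_returns_numerator(self):
        tree = ("div", x("x1"), x("x2"))
        assert evaluate_tree(tree, {"x1": 5.0, "x2": 0.0}) == 5.0
        assert evaluate_tree(tree, {"x1": 6.0, "x2": 2.0}) == 3.0

    def test_constant_tree_ignores_inputs(self):
        tree = ("add", c(2), c(3))
        assert evaluate_tree(tree, {"x1": 0.0}) == 5.0
        assert evaluate_tree(tree, {"x1": 99.0}) == 5.0

    def test_unknown_factor_raises(self):
        with pytest.raises(ValueError, match="x9"):
            evaluate_tree(x("x9"), {"x1": 1.0})

    def test_vectorised_matches_scalar(self):
        tree = ("sub", ("mul", x("a"), x("a")), ("div", c(1), x("b")))
        df = pd.DataFrame({"a": [0.0, 1.5, -2.0], "b": [1.0, 0.0, 4.0]})
        vec = evaluate_tree(tree, df)
        for i in range(3):
            assert vec[i] == pytest.approx(
                evaluate_tree(tree, {"a": df.a[i], "b": df.b[i]})
            )

    def test_depth_and_factor_helpers(self):
        tree = ("mul", ("add", x("x1"), c(1)), x("x2"))
        assert tree_depth(tree) == 2
        assert tree_factors(tree) == {"x1", "x2"}


class TestFitWeights:
    def test_exact_linear_fit(self):
        X = pd.DataFrame({"x": np.linspace(0, 5, 12)})
        y = 2.0 * X.x + 1.0
        w, b0, r2, adj, rmse = fit_weights([x("x")], X, y)
        assert w[0] == pytest.approx(2.0)
        assert b0 == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-10)

    def test_constant_gene_null_fit(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.uniform(0, 1, 40)})
        y = rng.normal(0, 1, 40)
        _, _, r2, _, _ = fit_weights([c(3.0)], X, y)
        assert r2 == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_genes_minimal_norm(self):
        """Rank-deficient design: finite weights, prediction unchanged."""
        X = pd.DataFrame({"x": np.linspace(-1, 3, 20)})
        y = 4.0 * X.x - 2.0
        w1, b1, r2_1, _, _ = fit_weights([x("x")], X, y)
        w2, b2, r2_2, _, _ = fit_weights([x("x"), x("x")], X, y)
        assert np.all(np.isfinite(w2))
        assert r2_2 == pytest.approx(r2_1)
        # minimal-norm pseudo-solution splits the weight across the copies
        pred1 = b1 + w1[0] * X.x
        pred2 = b2 + (w2[0] + w2[1]) * X.x
        assert np.allclose(pred1, pred2)

    def test_adjusted_r2_below_r2(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.uniform(0, 1, 30)})
        y = X.x + rng.normal(0, 0.3, 30)
        _, _, r2, adj, _ = fit_weights([x("x"), ("mul", x("x"), x("x"))], X, y)
        assert adj <= r2

    def test_nesting_never_hurts_rmse(self):
        """Adding a gene cannot increase least-squares training RMSE."""
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.uniform(-2, 2, 50), "b": rng.uniform(-2, 2, 50)})
        y = np.sin(X.a) + 0.5 * X.b
        genes = [x("a"), ("mul", x("a"), x("b")), ("div", x("b"), c(2)), x("b")]
        prev = np.inf
        for k in range(1, len(genes) + 1):
            *_, rmse = fit_weights(genes[:k], X, y)
            assert rmse <= prev + 1e-9
            prev = rmse

    def test_constant_response_convention(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        _, _, r2, _, _ = fit_weights([x("x")], X, [5.0, 5.0, 5.0])
        assert r2 == 1.0


class TestProtectedDivision:
    def test_vector_protection(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 0.0, 1e-15])
        out = _pdiv(a, b)
        assert out == pytest.approx([0.5, 2.0, 3.0])


class TestEvolveModels:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.uniform(0, 2, 30), "b": rng.uniform(0, 2, 30)})
        y = X.a * X.b + rng.normal(0, 0.1, 30)
        params = SRParams(population_size=30, generations=10, seed=11)
        m1 = evolve_models(X, y, params)
        m2 = evolve_models(X, y, params)
        assert m1.genes == m2.genes
        assert np.allclose(m1.weights, m2.weights)
        assert m1.rmse == m2.rmse

    def test_constant_target_trivial(self):
        X = pd.DataFrame({"a": np.linspace(0, 1, 10)})
        m = evolve_models(X, np.full(10, 7.0), SRParams(population_size=20, generations=2, seed=0))
        assert m.r2 == 1.0
        assert m.predict({"a": 0.3}) == pytest.approx(7.0)

    def test_predictions_finite_on_training_domain(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({c: rng.uniform(0, 10, 40) for c in "abc"})
        y = X.a / (1 + X.b) + rng.normal(0, 0.5, 40)
        m = evolve_models(X, y, SRParams(population_size=50, generations=15, seed=3))
        assert np.all(np.isfinite(m.predict(X)))

    def test_degenerate_data_rejected(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(DataError):
            evolve_models(X, [1.0, 2.0, 3.0], SRParams(population_size=10, generations=2, seed=0))

    def test_search_scaling_does_not_hurt(self):
        """A larger search budget does not lower the median best fit."""
        rng = np.random.default_rng(0)
        X = pd.DataFrame({c: rng.uniform(-2, 2, 64) for c in ("x1", "x2", "x3")})
        y = 3 * X.x1 + 2 * X.x1 * X.x2 - X.x3
        med = {}
        for pop, gens in [(30, 30), (100, 100)]:
            r2s = [
                evolve_models(X, y, SRParams(population_size=pop, generations=gens, seed=s)).r2
                for s in range(5)
            ]
            med[(pop, gens)] = np.median(r2s)
        assert med[(100, 100)] >= med[(30, 30)] - 1e-12


class TestBatchesAndMLR:
    def test_batch_sorted_and_sized(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 25), "b": rng.uniform(0, 1, 25)})
        y = X.a + rng.normal(0, 0.3, 25)
        batch = fit_batch(X, y, SRParams(population_size=20, generations=5, seed=0),
                          batch_size=4, objective="y")
        assert len(batch.models) == 4
        r2s = [m.r2 for m in batch.models]
        assert r2s == sorted(r2s, reverse=True)
        assert batch.best_r2 == max(r2s)
        # independent seeds: at least two distinct fits on noisy data
        assert len({round(m.rmse, 12) for m in batch.models}) >= 2

    def test_batch_of_one_equals_single_run(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 20)})
        y = 2 * X.a + rng.normal(0, 0.1, 20)
        params = SRParams(population_size=20, generations=5, seed=5)
        batch = fit_batch(X, y, params, batch_size=1)
        solo = evolve_models(
            X, y, params,
            rng=np.random.default_rng(np.random.SeedSequence(5).spawn(1)[0]),
        )
        assert batch.models[0].rmse == solo.rmse

    def test_mlr_exact_linear(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({c: rng.uniform(0, 1, 30) for c in "abc"})
        y = 1.0 + 2 * X.a - 3 * X.b + 0.5 * X.c
        mlr = fit_mlr(X, y)
        assert mlr.r2 == pytest.approx(1.0)
        assert mlr.predict({"a": 0.5, "b": 0.5, "c": 0.5}) == pytest.approx(
            1.0 + 1.0 - 1.5 + 0.25
        )

    def test_mlr_blind_to_pure_interaction(self):
        """y = x1*x2 on a symmetric grid: MLR sees nothing, SR can fit it."""
        g = np.linspace(-2, 2, 8)
        x1, x2 = np.meshgrid(g, g)
        X = pd.DataFrame({"x1": x1.ravel(), "x2": x2.ravel()})
        y = X.x1 * X.x2
        mlr = fit_mlr(X, y)
        assert mlr.r2 == pytest.approx(0.0, abs=1e-9)
        m = evolve_models(X, y, SRParams(population_size=100, generations=20, seed=0))
        assert m.r2 > 0.9

    def test_mlr_adjusted_r2_uses_factor_count(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({c: rng.uniform(0, 1, 20) for c in "ab"})
        y = X.a + rng.normal(0, 0.5, 20)
        mlr = fit_mlr(X, y)
        n, p = 20, 2
        assert mlr.adj_r2 == pytest.approx(1 - (1 - mlr.r2) * (n - 1) / (n - p - 1))
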