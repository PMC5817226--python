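"""Multigene genetic-programming symbolic regression.

Each candidate model is a small set of expression *genes* — trees over the
factors, real constants and the four basic operations {+, -, *, /} (division
protected near zero denominators) — combined linearly:

    y_hat = b0 + b1 * g1(x) + ... + bk * gk(x)

The gene weights ``b`` are re-fit by ordinary least squares every time a
model is evaluated, so evolution only has to discover useful *structures*;
the coefficients come for free.  Fitness is training RMSE.  Evolution uses
tournament selection, subtree crossover within a random gene, occasional
high-level gene swaps between models, subtree mutation and elitism.

A batch of independently seeded runs on the same dataset gives a pool of
models whose spread is later exploited by the sensitivity analysis; an
ordinary multiple-linear-regression baseline (:func:`fit_mlr`) is provided
for comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "SRParams",
    "GPModel",
    "ModelBatch",
    "MLRModel",
    "evaluate_tree",
    "tree_depth",
    "tree_factors",
    "fit_weights",
    "evolve_models",
    "fit_batch",
    "fit_mlr",
    "tree_to_sympy",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12

# A tree node is a tuple:  ("x", name) | ("c", value) | (op, left, right)
Node = tuple

_OPS = ("add", "sub", "mul", "div")


# ---------------------------------------------------------------- evaluation


def _pdiv(a, b):
    """Protected division: returns the numerator where |denominator| < 1e-12."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        q = a / b
    return np.where(np.abs(b) < _EPS, a, q)


def _eval(node: Node, cols: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    tag = node[0]
    if tag == "x":
        try:
            return cols[node[1]]
        except KeyError:
            raise ValueError(f"unknown factor reference {node[1]!r}") from None
    if tag == "c":
        return np.full(n, node[1])
    a = _eval(node[1], cols, n)
    b = _eval(node[2], cols, n)
    with np.errstate(over="ignore", invalid="ignore"):
        if tag == "add":
            return a + b
        if tag == "sub":
            return a - b
        if tag == "mul":
            return a * b
    if tag == "div":
        return _pdiv(a, b)
    raise ValueError(f"unknown node tag {tag!r}")


def evaluate_tree(
    tree: Node, x: Union[Mapping[str, float], pd.DataFrame]
) -> Union[float, np.ndarray]:
    """Evaluate an expression tree at a single condition or a table of them.

    ``x`` maps factor names to values (scalar evaluation) or is a DataFrame
    with one column per factor (vectorised evaluation).  Division by a
    near-zero denominator returns the numerator, so finite inputs always
    yield finite output for bounded trees.
    """
    if isinstance(x, pd.DataFrame):
        cols = {c: x[c].to_numpy(dtype=float) for c in x.columns}
        return _eval(tree, cols, len(x))
    cols = {k: np.asarray([float(v)]) for k, v in x.items()}
    return float(_eval(tree, cols, 1)[0])


def tree_depth(node: Node) -> int:
    """Operator depth: terminals are 0, each operator adds one level."""
    if node[0] in ("x", "c"):
        return 0
    return 1 + max(tree_depth(node[1]), tree_depth(node[2]))


def tree_factors(node: Node) -> set[str]:
    """Names of all factors referenced anywhere in the tree."""
    if node[0] == "x":
        return {node[1]}
    if node[0] == "c":
        return set()
    return tree_factors(node[1]) | tree_factors(node[2])


def _paths(node: Node, prefix: tuple[int, ...] = ()) -> list[tuple[int, ...]]:
    out = [prefix]
    if node[0] not in ("x", "c"):
        out += _paths(node[1], prefix + (1,))
        out += _paths(node[2], prefix + (2,))
    return out


def _get(node: Node, path: tuple[int, ...]) -> Node:
    for i in path:
        node = node[i]
    return node


def _replace(node: Node, path: tuple[int, ...], new: Node) -> Node:
    if not path:
        return new
    i = path[0]
    children = [node[1], node[2]]
    children[i - 1] = _replace(children[i - 1], path[1:], new)
    return (node[0], children[0], children[1])


def tree_to_sympy(node: Node):
    """Render a tree as a sympy expression (protected div as plain division)."""
    import sympy

    if node[0] == "x":
        return sympy.Symbol(node[1])
    if node[0] == "c":
        return sympy.Float(node[1])
    a, b = tree_to_sympy(node[1]), tree_to_sympy(node[2])
    return {
        "add": lambda: a + b,
        "sub": lambda: a - b,
        "mul": lambda: a * b,
        "div": lambda: a / b,
    }[node[0]]()


# ---------------------------------------------------------------- parameters


@dataclass(frozen=True)
class SRParams:
    """Search settings for the multigene GP.

    The defaults (population and generations of 500) suit datasets of the
    size produced by a few GA generations; smaller searches are adequate for
    smoke tests.  Operator probabilities (crossover / mutation /
    reproduction) must sum to 1.  ``p_gene_swap`` is the chance that a
    crossover event exchanges whole genes instead of subtrees, applied when
    both parents carry at least two genes.
    """

    population_size: int = 500
    generations: int = 500
    max_genes: int = 5
    max_depth: int = 4
    tournament_size: int = 2
    p_crossover: float = 0.85
    p_mutation: float = 0.10
    p_reproduction: float = 0.05
    p_gene_swap: float = 0.2
    elite: int = 1
    p_constant: float = 0.2
    const_range: tuple[float, float] = (-5.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")
        if self.max_genes < 1 or self.max_depth < 1:
            raise ValueError("max_genes and max_depth must be >= 1")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        p = self.p_crossover + self.p_mutation + self.p_reproduction
        if abs(p - 1.0) > 1e-9:
            raise ValueError(f"operator probabilities sum to {p}, expected 1")
        if self.elite < 0:
            raise ValueError("elite must be >= 0")


# ------------------------------------------------------------------- models


@dataclass
class GPModel:
    """A fitted multigene model: trees + least-squares weights + fit stats."""

    factor_names: list[str]
    genes: list[Node]
    weights: np.ndarray  # one per gene
    intercept: float
    r2: float
    adj_r2: float
    rmse: float

    def predict(
        self, x: Union[Mapping[str, float], pd.DataFrame]
    ) -> Union[float, np.ndarray]:
        scalar = not isinstance(x, pd.DataFrame)
        if scalar:
            x = pd.DataFrame([{k: float(v) for k, v in x.items()}])
        missing = set().union(*(tree_factors(g) for g in self.genes)) - set(x.columns)
        if missing:
            raise ValueError(f"prediction input missing factors {sorted(missing)}")
        out = np.full(len(x), self.intercept, dtype=float)
        for w, g in zip(self.weights, self.genes):
            out = out + w * np.asarray(evaluate_tree(g, x), dtype=float)
        return float(out[0]) if scalar else out

    def expression(self, digits: int = 4):
        """Human-readable simplified sympy expression of the whole model."""
        import sympy

        expr = sympy.Float(self.intercept)
        for w, g in zip(self.weights, self.genes):
            expr = expr + sympy.Float(w) * tree_to_sympy(g)
        return sympy.nsimplify(sympy.expand(expr), rational=False).evalf(digits)

    def to_dict(self) -> dict:
        return {
            "factor_names": self.factor_names,
            "genes": [_node_to_json(g) for g in self.genes],
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
            "r2": float(self.r2),
            "adj_r2": float(self.adj_r2),
            "rmse": float(self.rmse),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPModel":
        return cls(
            factor_names=list(d["factor_names"]),
            genes=[_node_from_json(g) for g in d["genes"]],
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            r2=float(d["r2"]),
            adj_r2=float(d["adj_r2"]),
            rmse=float(d["rmse"]),
        )


def _node_to_json(node: Node):
    if node[0] in ("x", "c"):
        return list(node)
    return [node[0], _node_to_json(node[1]), _node_to_json(node[2])]


def _node_from_json(obj) -> Node:
    if obj[0] == "x":
        return ("x", obj[1])
    if obj[0] == "c":
        return ("c", float(obj[1]))
    return (obj[0], _node_from_json(obj[1]), _node_from_json(obj[2]))


@dataclass
class ModelBatch:
    """Independently evolved models for one objective, same training data."""

    objective: str
    models: list[GPModel] = field(default_factory=list)

    @property
    def best(self) -> GPModel:
        return self.models[0]

    @property
    def best_r2(self) -> float:
        return self.models[0].r2

    def to_dict(self) -> dict:
        return {
            "objective": self.objective,
            "models": [m.to_dict() for m in self.models],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelBatch":
        return cls(d["objective"], [GPModel.from_dict(m) for m in d["models"]])


@dataclass
class MLRModel:
    """Ordinary multiple linear regression baseline on the raw factor values."""

    factor_names: list[str]
    coef: np.ndarray
    intercept: float
    r2: float
    adj_r2: float

    def predict(self, x: Union[Mapping[str, float], pd.DataFrame]):
        scalar = not isinstance(x, pd.DataFrame)
        if scalar:
            x = pd.DataFrame([{k: float(v) for k, v in x.items()}])
        X = x[self.factor_names].to_numpy(dtype=float)
        out = self.intercept + X @ self.coef
        return float(out[0]) if scalar else out


# ------------------------------------------------------------ weight fitting


def _design_matrix(genes: Sequence[Node], X: pd.DataFrame) -> np.ndarray:
    n = len(X)
    cols = {c: X[c].to_numpy(dtype=float) for c in X.columns}
    A = np.empty((n, len(genes) + 1))
    A[:, 0] = 1.0
    for j, g in enumerate(genes):
        A[:, j + 1] = _eval(g, cols, n)
    return A


def _r2_stats(y: np.ndarray, resid: np.ndarray, p: int) -> tuple[float, float]:
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        logger.warning("constant response: R^2 set to %s", 1.0 if ss_res < 1e-12 else 0.0)
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    n = y.size
    if n - p - 1 > 0:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    else:
        adj = float("nan")
    return r2, adj


def fit_weights(
    genes: Sequence[Node], X: pd.DataFrame, y: Sequence[float]
) -> tuple[np.ndarray, float, float, float, float]:
    """Least-squares gene weights and fit statistics.

    Returns ``(weights, intercept, r2, adj_r2, rmse)``.  A rank-deficient
    design (e.g. duplicate genes) is resolved by the minimal-norm solution,
    so predictions are well defined regardless.  Adjusted R^2 uses p = number
    of genes.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 1:
        raise DataError("weight fitting needs at least one data row")
    if not np.all(np.isfinite(y)):
        raise DataError("response contains non-finite values")
    A = _design_matrix(genes, X)
    if not np.all(np.isfinite(A)):
        raise DataError("gene outputs are non-finite on the training data")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    r2, adj = _r2_stats(y, resid, p=len(genes))
    rmse = float(np.sqrt((resid @ resid) / y.size))
    return coef[1:], float(coef[0]), r2, adj, rmse


# ---------------------------------------------------------------- evolution


def _random_tree(
    rng: np.random.Generator,
    depth: int,
    factor_names: Sequence[str],
    params: SRParams,
    method: str,
) -> Node:
    if depth <= 0 or (method == "grow" and rng.random() < 0.3):
        if rng.random() < params.p_constant:
            lo, hi = params.const_range
            return ("c", float(rng.uniform(lo, hi)))
        return ("x", factor_names[int(rng.integers(len(factor_names)))])
    op = _OPS[int(rng.integers(len(_OPS)))]
    return (
        op,
        _random_tree(rng, depth - 1, factor_names, params, method),
        _random_tree(rng, depth - 1, factor_names, params, method),
    )


def _random_individual(
    rng: np.random.Generator, factor_names: Sequence[str], params: SRParams, k: int
) -> list[Node]:
    # ramped half-and-half: cycle depths 2..max_depth, alternate grow/full
    depths = list(range(2, params.max_depth + 1)) or [1]
    depth = depths[k % len(depths)]
    method = "grow" if (k // len(depths)) % 2 == 0 else "full"
    n_genes = int(rng.integers(1, params.max_genes + 1))
    return [
        _random_tree(rng, depth, factor_names, params, method)
        for _ in range(n_genes)
    ]


def _model_fitness(
    genes: list[Node], X: pd.DataFrame, y: np.ndarray, cols, n
) -> tuple[float, Optional[tuple]]:
    """RMSE after weight fitting; inf when the design is non-finite."""
    A = np.empty((n, len(genes) + 1))
    A[:, 0] = 1.0
    for j, g in enumerate(genes):
        A[:, j + 1] = _eval(g, cols, n)
    if not np.all(np.isfinite(A)):
        return float("inf"), None
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    rmse = float(np.sqrt((resid @ resid) / n))
    if not math.isfinite(rmse):
        return float("inf"), None
    return rmse, (coef[1:], float(coef[0]), resid)


def _tournament(
    rng: np.random.Generator, fitnesses: list[float], k: int
) -> int:
    idx = rng.integers(len(fitnesses), size=k)
    return int(min(idx, key=lambda i: fitnesses[i]))


def _subtree_crossover(
    rng: np.random.Generator, p1: list[Node], p2: list[Node], params: SRParams
) -> list[Node]:
    child = list(p1)
    gi = int(rng.integers(len(child)))
    donor = p2[int(rng.integers(len(p2)))]
    path = _paths(child[gi])[int(rng.integers(len(_paths(child[gi]))))]
    dpaths = _paths(donor)
    dsub = _get(donor, dpaths[int(rng.integers(len(dpaths)))])
    new_gene = _replace(child[gi], path, dsub)
    if tree_depth(new_gene) <= params.max_depth:
        child[gi] = new_gene
    return child


def _gene_swap(
    rng: np.random.Generator, p1: list[Node], p2: list[Node]
) -> list[Node]:
    child = list(p1)
    child[int(rng.integers(len(child)))] = p2[int(rng.integers(len(p2)))]
    return child


def _subtree_mutation(
    rng: np.random.Generator,
    parent: list[Node],
    factor_names: Sequence[str],
    params: SRParams,
) -> list[Node]:
    child = list(parent)
    gi = int(rng.integers(len(child)))
    paths = _paths(child[gi])
    path = paths[int(rng.integers(len(paths)))]
    new_sub = _random_tree(rng, int(rng.integers(1, 3)), factor_names, params, "grow")
    new_gene = _replace(child[gi], path, new_sub)
    if tree_depth(new_gene) <= params.max_depth:
        child[gi] = new_gene
    return child


def evolve_models(
    X: pd.DataFrame,
    y: Sequence[float],
    params: SRParams,
    rng: Optional[np.random.Generator] = None,
) -> GPModel:
    """Evolve one multigene model; identical seeds give identical models.

    ``X`` holds one column per factor (raw physical units, no
    standardisation), ``y`` the aggregated objective response.  The model
    minimising training RMSE across all generations is returned with its
    least-squares weights and fit statistics.
    """
    y = np.asarray(y, dtype=float)
    if len(X) < 2 or np.unique(y).size < 1 or len(X) != y.size:
        raise DataError("need >= 2 data rows with matching response length")
    if np.unique(X.to_numpy(dtype=float), axis=0).shape[0] < 2:
        raise DataError("training data must contain >= 2 distinct conditions")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    factor_names = list(X.columns)
    cols = {c: X[c].to_numpy(dtype=float) for c in factor_names}
    n = len(X)

    pop = [
        _random_individual(rng, factor_names, params, k)
        for k in range(params.population_size)
    ]
    fits = [ _model_fitness(ind, X, y, cols, n)[0] for ind in pop ]
    best_ind, best_fit = min(zip(pop, fits), key=lambda t: t[1])

    for _gen in range(params.generations - 1):
        order = sorted(range(len(pop)), key=lambda i: fits[i])
        new_pop = [list(pop[order[i]]) for i in range(params.elite)]
        while len(new_pop) < params.population_size:
            r = rng.random()
            if r < params.p_crossover:
                i1 = _tournament(rng, fits, params.tournament_size)
                i2 = _tournament(rng, fits, params.tournament_size)
                p1, p2 = pop[i1], pop[i2]
                if (
                    len(p1) >= 2
                    and len(p2) >= 2
                    and rng.random() < params.p_gene_swap
                ):
                    child = _gene_swap(rng, p1, p2)
                else:
                    child = _subtree_crossover(rng, p1, p2, params)
            elif r < params.p_crossover + params.p_mutation:
                i1 = _tournament(rng, fits, params.tournament_size)
                child = _subtree_mutation(rng, pop[i1], factor_names, params)
            else:
                i1 = _tournament(rng, fits, params.tournament_size)
                child = list(pop[i1])
            new_pop.append(child)
        pop = new_pop
        fits = [ _model_fitness(ind, X, y, cols, n)[0] for ind in pop ]
        gen_best_i = min(range(len(pop)), key=lambda i: fits[i])
        if fits[gen_best_i] < best_fit:
            best_fit = fits[gen_best_i]
            best_ind = list(pop[gen_best_i])

    weights, intercept, r2, adj, rmse = fit_weights(best_ind, X, y)
    return GPModel(
        factor_names=factor_names,
        genes=list(best_ind),
        weights=weights,
        intercept=intercept,
        r2=r2,
        adj_r2=adj,
        rmse=rmse,
    )


def fit_batch(
    X: pd.DataFrame,
    y: Sequence[float],
    params: SRParams,
    batch_size: int = 10,
    objective: str = "y",
) -> ModelBatch:
    """``batch_size`` independent runs with derived seeds, sorted by R^2."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    seeds = np.random.SeedSequence(params.seed).spawn(batch_size)
    models = [
        evolve_models(X, y, params, rng=np.random.default_rng(s)) for s in seeds
    ]
    models.sort(key=lambda m: -m.r2)
    return ModelBatch(objective, models)


def fit_mlr(X: pd.DataFrame, y: Sequence[float]) -> MLRModel:
    """Multiple linear regression of y on the raw factor values.

    Adjusted R^2 uses p = number of factors.  A singular design is solved by
    the minimal-norm (pseudoinverse) solution with a warning.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    Xm = X.to_numpy(dtype=float)
    if len(X) <= Xm.shape[1] + 1:
        raise DataError(
            f"MLR needs more rows ({len(X)}) than factors + 1 ({Xm.shape[1] + 1})"
        )
    A = sm.add_constant(Xm, has_constant="add")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        logger.warning("singular MLR design; minimal-norm solution used")
    res = sm.OLS(y, A).fit()
    coef = np.asarray(res.params)
    r2 = float(res.rsquared)
    p = Xm.shape[1]
    n = y.size
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return MLRModel(
        factor_names=list(X.columns),
        coef=coef[1:],
        intercept=float(coef[0]),
        r2=r2,
        adj_r2=float(adj),
    )
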