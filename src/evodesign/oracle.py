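"""A simulated wet lab: replicate responses for any proposed condition set.

The oracle mimics the statistical structure of a small-culture medium
optimisation study — here, methanol-induced recombinant-protein production
in a methylotrophic yeast: nine factors (eight medium components plus pH),
four objectives (pre-induction biomass, induction-phase biomass gain to be
minimised, secreted enzyme activity, specific productivity), triplicate
measurements with multiplicative lognormal noise, and occasional single
missing values.  Response surfaces combine Monod-style saturating uptake
terms, Gaussian optima (pH bell, glycerol optimum for induction) and a ratio
interaction (specific productivity = activity per unit biomass), so some
factors are genuinely null, linear regression underfits, and the declared
optimum is a meaningful recovery target for end-to-end tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from itertools import product
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .design_space import DesignSpace, FactorSpec, ObjectiveSpec
from .errors import DataError

__all__ = ["SyntheticOracle", "case_study_oracle", "tiny_oracle", "bell", "sat"]


def bell(x: float, mu: float, sigma: float) -> float:
    """Gaussian response bell: exp(-(x - mu)^2 / (2 sigma^2))."""
    return math.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def sat(x: float, K: float) -> float:
    """Monod / Michaelis-Menten saturation: x / (K + x)."""
    return x / (K + x)


@dataclass
class SyntheticOracle:
    """Deterministic response surfaces plus a stochastic measurement layer.

    Parameters
    ----------
    space:
        Factors and objectives of the emulated study.
    response_fns:
        Noiseless response per objective: ``condition dict -> float``.
    noise_cv:
        Coefficient of variation of the replicate noise (0.1 default).
    replicates:
        Replicates per condition (3 default).
    missing_prob:
        Per-replicate-cell blanking probability; never more than one
        replicate per (condition, objective) is blanked, so every cell stays
        repairable by the single-missing-value rule.
    drivers:
        Ground-truth metadata: objective -> factors that dominate its
        response near the optimum (used by recovery tests).
    noise_kind:
        ``"lognormal"`` (mean-one multiplicative, default) or ``"gaussian"``
        (additive, sd = cv * |noiseless|).
    """

    space: DesignSpace
    response_fns: dict[str, Callable[[Mapping[str, float]], float]]
    noise_cv: float = 0.1
    replicates: int = 3
    missing_prob: float = 0.02
    seed: int = 0
    drivers: dict[str, frozenset[str]] = field(default_factory=dict)
    null_factors: frozenset[str] = frozenset()
    not_applicable: dict[str, tuple[str, ...]] = field(default_factory=dict)
    noise_kind: str = "lognormal"

    def __post_init__(self) -> None:
        missing = [o.name for o in self.space.objectives if o.name not in self.response_fns]
        if missing:
            raise ValueError(f"no response function for objectives {missing}")
        if self.noise_kind not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must be in [0, 1)")

    # ------------------------------------------------------------ noiseless

    def noiseless(self, condition: Mapping[str, float]) -> dict[str, float]:
        """Deterministic response of every objective at one condition."""
        return {name: fn(condition) for name, fn in self.response_fns.items()}

    # -------------------------------------------------- grid optimisation

    def _grid_conditions(self):
        return self.space.iter_grid()

    def _coordinate_search(
        self, fn: Callable[[Mapping[str, float]], float], maximize: bool,
        n_restarts: int = 6,
    ) -> tuple[dict[str, float], float]:
        """Deterministic multi-start coordinate ascent over the level grid."""
        factors = self.space.factors
        rng = np.random.default_rng(12345)  # fixed: search is part of the spec
        sign = 1.0 if maximize else -1.0
        starts = [tuple(f.n_levels // 2 for f in factors)]
        starts += [
            tuple(int(rng.integers(f.n_levels)) for f in factors)
            for _ in range(n_restarts - 1)
        ]
        best_val, best_cond = -math.inf, None
        for start in starts:
            ks = list(start)
            cond = {f.name: f.level_value(k) for f, k in zip(factors, ks)}
            val = sign * fn(cond)
            for _sweep in range(50):
                changed = False
                for i, f in enumerate(factors):
                    for k in range(f.n_levels):
                        if k == ks[i]:
                            continue
                        trial = dict(cond)
                        trial[f.name] = f.level_value(k)
                        v = sign * fn(trial)
                        if v > val:
                            val, ks[i], cond, changed = v, k, trial, True
                if not changed:
                    break
            if val > best_val:
                best_val, best_cond = val, cond
        return best_cond, sign * best_val

    def _extremes(
        self, fn: Callable[[Mapping[str, float]], float]
    ) -> tuple[float, float]:
        if self.space.grid_size <= 65536:
            vals = [fn(c) for c in self._grid_conditions()]
            return min(vals), max(vals)
        _, hi = self._coordinate_search(fn, maximize=True)
        _, lo = self._coordinate_search(fn, maximize=False)
        return lo, hi

    @cached_property
    def objective_bounds(self) -> dict[str, tuple[float, float]]:
        """Per-objective (min, max) of the noiseless response over the grid."""
        return {name: self._extremes(fn) for name, fn in self.response_fns.items()}

    def composite_score(self, condition: Mapping[str, float]) -> float:
        """Weighted normalised noiseless score with grid-wide extremes.

        The same form as the GA's per-generation fitness, but normalised
        against the full representable grid so that scores of different
        conditions are comparable; used as the ground truth in recovery
        tests.
        """
        total = 0.0
        vals = self.noiseless(condition)
        for obj in self.space.objectives:
            lo, hi = self.objective_bounds[obj.name]
            if hi == lo:
                t = 0.5
            else:
                t = (vals[obj.name] - lo) / (hi - lo)
                t = min(max(t, 0.0), 1.0)
                if obj.direction == "minimize":
                    t = 1.0 - t
            total += obj.weight * t
        return total

    @cached_property
    def _optimum(self) -> tuple[dict[str, float], float]:
        if self.space.grid_size <= 65536:
            best = max(self._grid_conditions(), key=self.composite_score)
            return best, self.composite_score(best)
        return self._coordinate_search(self.composite_score, maximize=True)

    def true_optimum(self) -> tuple[dict[str, float], dict[str, float]]:
        """Declared grid optimum of the composite and its noiseless responses.

        Found by exhaustive enumeration when the grid is small enough,
        otherwise by deterministic multi-start coordinate ascent.
        """
        cond, _ = self._optimum
        return dict(cond), self.noiseless(cond)

    # ------------------------------------------------------------ measuring

    def respond(
        self,
        design: pd.DataFrame,
        rng: Optional[np.random.Generator] = None,
    ) -> pd.DataFrame:
        """Simulated replicate measurements for a proposed design table.

        ``design`` needs a ``condition_id`` column plus one column per
        factor.  Returns the results-table schema consumed by the session:
        ``condition_id, replicate, <objective>...`` with NaN marking missing
        cells.  Re-running with the same design and seed reproduces the file
        exactly.
        """
        required = ["condition_id"] + self.space.factor_names
        missing = [c for c in required if c not in design.columns]
        if missing:
            raise DataError(f"design table lacks columns {missing}")
        if rng is None:
            rng = np.random.default_rng(self.seed)
        obj_names = self.space.objective_names
        sigma = math.sqrt(math.log(1.0 + self.noise_cv**2))
        rows = []
        for _, drow in design.iterrows():
            cond = {f: float(drow[f]) for f in self.space.factor_names}
            clean = self.noiseless(cond)
            for rep in range(1, self.replicates + 1):
                row: dict[str, object] = {
                    "condition_id": drow["condition_id"],
                    "replicate": rep,
                }
                for o in obj_names:
                    mu = clean[o]
                    if self.noise_cv > 0:
                        if self.noise_kind == "lognormal":
                            v = mu * math.exp(rng.normal(-sigma**2 / 2.0, sigma))
                        else:
                            v = mu + rng.normal(0.0, self.noise_cv * abs(mu))
                    else:
                        v = mu
                    row[o] = v
                rows.append(row)
            # blank at most one replicate per (condition, objective)
            for o in obj_names:
                hits = [r for r in range(self.replicates)
                        if rng.random() < self.missing_prob]
                if hits and self.replicates >= 2:
                    rows[len(rows) - self.replicates + hits[0]][o] = np.nan
        return pd.DataFrame(rows)


# ------------------------------------------------------------- constructors


def case_study_oracle(
    bits: int = 3,
    noise_cv: float = 0.1,
    missing_prob: float = 0.02,
    seed: int = 0,
) -> SyntheticOracle:
    """Nine-factor, four-objective oracle emulating an induced-yeast culture.

    Factors: eight medium components (g/l) and pH.  The encoded grid uses
    ``bits`` per factor (3 by default so tests stay enumerable per factor;
    pass 5 for a case-study-sized 32-level grid).

    Ground truth built into the surfaces: pre-induction biomass saturates in
    glycerol and ammonium with a mildly acidic pH optimum; induction-phase
    biomass gain grows with leftover carbon (glycerol, sorbitol) and
    methanol; secreted enzyme activity scales superlinearly with the carbon
    budget and needs near-neutral pH for stability, and benefits mildly from
    methanol; specific productivity is activity per unit harvest biomass.
    Potassium, magnesium and iron are null factors.  Because growth and
    product objectives pull pH and glycerol in opposing directions, the
    composite optimum sits on the flanks (not the peaks) of the individual
    responses, so a +/-10 % factor shift there produces a clearly nonzero
    response in each driving objective — the regime the sensitivity
    analysis is designed to detect.
    """
    factors = (
        FactorSpec("ammonium", 0.0, 10.0, bits, "g/l"),
        FactorSpec("potassium", 0.0, 10.0, bits, "g/l"),
        FactorSpec("magnesium", 0.0, 10.0, bits, "g/l"),
        FactorSpec("iron", 0.0, 1.0, bits, "g/l"),
        FactorSpec("calcium", 0.0, 5.0, bits, "g/l"),
        FactorSpec("glycerol", 0.0, 20.0, bits, "g/l"),
        FactorSpec("methanol", 0.0, 15.0, bits, "g/l"),
        FactorSpec("sorbitol", 0.0, 30.0, bits, "g/l"),
        FactorSpec("ph", 2.6, 7.0, bits, "pH"),
    )
    objectives = (
        ObjectiveSpec("od_pre", "maximize", 0.25),
        ObjectiveSpec("od_gain", "minimize", 0.25),
        ObjectiveSpec("enzyme_activity", "maximize", 0.25),
        ObjectiveSpec("specific_productivity", "maximize", 0.25),
    )
    space = DesignSpace(factors, objectives)

    def od_pre(c):
        return 2.0 + 16.0 * sat(c["glycerol"], 6.0) * sat(c["ammonium"], 1.5) * bell(
            c["ph"], 4.8, 1.2
        )

    def od_gain(c):
        return (
            0.4
            + 0.12 * c["glycerol"]
            + 0.05 * c["sorbitol"]
            + 0.8 * sat(c["methanol"], 3.0)
        )

    def enzyme_activity(c):
        # secreted activity ~ biomass x per-cell synthesis (carbon budget,
        # near-neutral pH stability, methanol induction boost)
        return 5.0 + 0.04 * od_pre(c) * c["glycerol"] ** 2 * bell(
            c["ph"], 6.5, 0.9
        ) * (0.75 + 0.25 * sat(c["methanol"], 2.0))

    def specific_productivity(c):
        return enzyme_activity(c) / (od_pre(c) + od_gain(c))

    return SyntheticOracle(
        space=space,
        response_fns={
            "od_pre": od_pre,
            "od_gain": od_gain,
            "enzyme_activity": enzyme_activity,
            "specific_productivity": specific_productivity,
        },
        noise_cv=noise_cv,
        missing_prob=missing_prob,
        seed=seed,
        drivers={
            "od_pre": frozenset({"glycerol", "ammonium", "ph"}),
            "od_gain": frozenset({"glycerol", "sorbitol", "methanol"}),
            "enzyme_activity": frozenset({"ph", "glycerol"}),
            "specific_productivity": frozenset({"ph", "glycerol"}),
        },
        null_factors=frozenset({"potassium", "magnesium", "iron"}),
        not_applicable={"od_pre": ("methanol", "sorbitol")},
    )


def tiny_oracle(
    bits: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
    gray_code: bool = False,
) -> SyntheticOracle:
    """Two-factor single-objective oracle with a fully enumerable grid.

    64 conditions at the default 3 bits; noiseless by default so GA runs can
    be checked against brute-force enumeration of the grid.  ``gray_code``
    switches the chromosome encoding so that adjacent levels differ by one
    bit — the recommended setting when single-bit mutation is the main
    exploration operator on a small grid.
    """
    factors = (
        FactorSpec("glycerol", 0.0, 20.0, bits, "g/l"),
        FactorSpec("ph", 2.6, 7.0, bits, "pH"),
    )
    objectives = (ObjectiveSpec("enzyme_activity", "maximize", 1.0),)
    space = DesignSpace(factors, objectives, gray_code=gray_code)

    def enzyme_activity(c):
        # broad unimodal surface: informative gradient over the whole grid
        return 5.0 + 150.0 * bell(c["ph"], 6.0, 1.6) * bell(c["glycerol"], 12.0, 7.0)

    return SyntheticOracle(
        space=space,
        response_fns={"enzyme_activity": enzyme_activity},
        noise_cv=noise_cv,
        missing_prob=0.0,
        seed=seed,
        drivers={"enzyme_activity": frozenset({"ph", "glycerol"})},
    )
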