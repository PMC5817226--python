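"""Perturbation-based sensitivity analysis over model batches.

Each factor is shifted +/-10 % (configurable) from its determined optimum
while holding the others fixed; the relative change in each surrogate
model's prediction is recorded, and a factor is declared a *major
contributor* to an objective when enough of the batch's models (majority by
default) respond by at least the threshold (10 % by default).  Factors that
are physically absent from a phase (e.g. inducer carbon sources before
induction) are excluded and reported as not-applicable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import StateError
from .symreg import ModelBatch

__all__ = ["SensitivityReport", "perturb_and_score", "classify_contributors"]

logger = logging.getLogger(__name__)

INFINITE_RESPONSE = float("inf")


def perturb_and_score(
    batch: ModelBatch,
    optimum: Mapping[str, float],
    factor: str,
    delta: float = 0.10,
) -> list[float]:
    """Relative prediction response of each model to a +/-delta factor shift.

    For each model, the factor value at the optimum is scaled by (1 + delta)
    and (1 - delta) in turn and the larger relative prediction change
    ``max(|y+ - y0|, |y- - y0|) / |y0|`` is reported.  A near-zero baseline
    prediction yields an infinite sentinel (with a warning) rather than a
    division error.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if not batch.models:
        raise StateError(f"empty model batch for objective {batch.objective!r}")
    if factor not in batch.models[0].factor_names:
        raise ValueError(f"unknown factor {factor!r}")
    missing = [f for f in batch.models[0].factor_names if f not in optimum]
    if missing:
        raise ValueError(f"optimum does not cover factors {missing}")
    base = {k: float(v) for k, v in optimum.items()}
    up = dict(base)
    up[factor] = base[factor] * (1 + delta)
    down = dict(base)
    down[factor] = base[factor] * (1 - delta)
    responses = []
    for model in batch.models:
        y0 = model.predict(base)
        if abs(y0) < 1e-12:
            logger.warning(
                "near-zero baseline prediction for objective %r; "
                "infinite response sentinel reported", batch.objective,
            )
            responses.append(INFINITE_RESPONSE)
            continue
        dy = max(abs(model.predict(up) - y0), abs(model.predict(down) - y0))
        responses.append(dy / abs(y0))
    return responses


def _flag(responses: Sequence[float], threshold: float, rule: str) -> bool:
    hits = sum(1 for r in responses if r >= threshold)
    if rule == "any":
        return hits >= 1
    if rule == "majority":
        return hits >= math.ceil(len(responses) / 2)
    if rule == "all":
        return hits == len(responses)
    raise ValueError(f"unknown batch_rule {rule!r}")


@dataclass
class SensitivityReport:
    """Per (objective, factor) responses, contributor flags and n/a markers."""

    responses: dict[tuple[str, str], list[float]]
    major: dict[tuple[str, str], bool]
    not_applicable: set[tuple[str, str]] = field(default_factory=set)
    threshold: float = 0.10
    batch_rule: str = "majority"

    def grid(self) -> pd.DataFrame:
        """Objective x factor table of 'yes' / '' / 'n/a' flags."""
        objectives = sorted({o for o, _ in set(self.major) | self.not_applicable})
        factors = sorted({f for _, f in set(self.major) | self.not_applicable})
        data = {}
        for f in factors:
            col = []
            for o in objectives:
                if (o, f) in self.not_applicable:
                    col.append("n/a")
                else:
                    col.append("yes" if self.major.get((o, f), False) else "")
            data[f] = col
        return pd.DataFrame(data, index=objectives).T

    def contributors(self, objective: str) -> list[str]:
        return sorted(
            f for (o, f), flag in self.major.items() if o == objective and flag
        )


def classify_contributors(
    batches: Sequence[ModelBatch],
    optimum: Mapping[str, float],
    delta: float = 0.10,
    threshold: float = 0.10,
    batch_rule: str = "majority",
    not_applicable: Optional[Mapping[str, Sequence[str]]] = None,
) -> SensitivityReport:
    """Classify factors as major contributors per objective.

    ``not_applicable`` maps objective name -> factors to exclude for that
    objective (reported as 'n/a' in the grid).  With the default majority
    rule a factor is flagged when at least half of the batch's models show a
    relative response >= ``threshold`` to the +/-``delta`` shift.
    """
    na = {
        (obj, f)
        for obj, fs in (not_applicable or {}).items()
        for f in fs
    }
    responses: dict[tuple[str, str], list[float]] = {}
    major: dict[tuple[str, str], bool] = {}
    for batch in batches:
        if not batch.models:
            raise StateError(f"empty model batch for objective {batch.objective!r}")
        for factor in batch.models[0].factor_names:
            key = (batch.objective, factor)
            if key in na:
                continue
            resp = perturb_and_score(batch, optimum, factor, delta)
            responses[key] = resp
            major[key] = _flag(resp, threshold, batch_rule)
    return SensitivityReport(
        responses=responses,
        major=major,
        not_applicable=na,
        threshold=threshold,
        batch_rule=batch_rule,
    )
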