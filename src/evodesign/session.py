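"""File-backed interactive optimisation session.

The session mirrors the bench workflow: configure once, then repeat
``propose`` (export a design CSV for the lab), ``ingest`` (read back the
replicate measurements, compute fitness) and ``step`` (breed the next
generation and print convergence advice) until the experimenter decides to
stop.  All state lives in a versioned JSON file; the configuration is locked
by hash after ``init``, ingest is atomic (a rejected results file leaves the
state byte-identical), and every stochastic draw derives from the recorded
session seed, so a session replays bit-identically from its inputs.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .config import StudyConfig, build_spaces, config_hash, load_config
from .design_space import Chromosome
from .diagnostics import (
    better_fraction_scores,
    improvement_test,
    relative_standard_deviation,
    score_trajectories,
)
from .errors import DataError, StateError
from .ga import (
    FitnessResult,
    GenerationRecord,
    MeasurementTable,
    aggregate_replicates,
    evaluate_fitness,
    next_generation,
    random_population,
)
from .simulate import derived_seed, design_table, history_dataset

__all__ = ["Session"]

STATE_VERSION = 1


class Session:
    """One optimisation study bound to a JSON state file."""

    def __init__(
        self,
        cfg: StudyConfig,
        state_path: Union[str, Path],
        history: Optional[list[GenerationRecord]] = None,
        audit: Optional[list[dict]] = None,
    ) -> None:
        self.cfg = cfg
        self.state_path = Path(state_path)
        self.space, self.params = build_spaces(cfg)
        self.seed = cfg.seed
        self.history: list[GenerationRecord] = history or []
        self.audit: list[dict] = audit or []

    # ----------------------------------------------------------- lifecycle

    @classmethod
    def init(
        cls,
        config: Union[str, Path, dict],
        state_path: Union[str, Path],
        seed: Optional[int] = None,
        force: bool = False,
    ) -> "Session":
        """Create a session and propose generation 1.

        Refuses to overwrite an existing state file unless ``force`` is set.
        """
        state_path = Path(state_path)
        if state_path.exists() and not force:
            raise StateError(
                f"state file {state_path} already exists; use force to re-init"
            )
        cfg = load_config(config)
        if seed is not None:
            cfg = cfg.model_copy(update={"seed": int(seed)})
        session = cls(cfg, state_path)
        gen_seed = derived_seed(session.seed, 1)
        record = random_population(
            session.space, session.params, np.random.default_rng(gen_seed)
        )
        record.seed = gen_seed
        session.history.append(record)
        session._log("init", 1, {"seed": session.seed, "gen_seed": gen_seed})
        session.save()
        return session

    @classmethod
    def load(cls, state_path: Union[str, Path]) -> "Session":
        state_path = Path(state_path)
        if not state_path.exists():
            raise StateError(f"no state file at {state_path}")
        state = json.loads(state_path.read_text())
        if state.get("version") != STATE_VERSION:
            raise StateError(
                f"unsupported state version {state.get('version')!r}"
            )
        cfg = StudyConfig.model_validate(state["config"])
        if config_hash(cfg) != state["config_hash"]:
            raise StateError("state file corrupt: configuration hash mismatch")
        history = [_record_from_json(g) for g in state["history"]]
        return cls(cfg, state_path, history=history, audit=list(state["audit"]))

    def save(self) -> None:
        """Atomic write: serialise to a temp file, then rename into place."""
        state = {
            "version": STATE_VERSION,
            "config": self.cfg.model_dump(),
            "config_hash": config_hash(self.cfg),
            "seed": self.seed,
            "history": [_record_to_json(g) for g in self.history],
            "audit": self.audit,
        }
        tmp = self.state_path.with_suffix(".tmp")
        tmp.write_text(json.dumps(state, sort_keys=True, indent=1))
        os.replace(tmp, self.state_path)

    def _log(self, op: str, generation: int, detail: Optional[dict] = None) -> None:
        self.audit.append(
            {
                "seq": len(self.audit) + 1,
                "op": op,
                "generation": generation,
                "detail": detail or {},
            }
        )

    # ------------------------------------------------------------ workflow

    @property
    def current(self) -> GenerationRecord:
        return self.history[-1]

    def propose(self, path: Optional[Union[str, Path]] = None) -> pd.DataFrame:
        """Design table of the current generation's physical conditions.

        Idempotent until results are ingested; values in the CSV are printed
        with 4 significant digits (full precision stays in the state file).
        """
        if self.current.fitness is not None:
            raise StateError(
                "results already ingested for this generation; run step"
            )
        design = design_table(self.space, self.current)
        if path is not None:
            design.to_csv(path, index=False, float_format="%.4g")
        return design

    def ingest(self, results: Union[str, Path, pd.DataFrame]) -> FitnessResult:
        """Validate and store a results table, then compute fitness.

        Validation is all-or-nothing: on any error (unknown or missing
        condition ids, non-numeric fields, unrepairable missing replicates)
        the session state is left untouched.
        """
        record = self.current
        if record.fitness is not None:
            raise StateError("results already ingested for this generation")
        if isinstance(results, (str, Path)):
            df = pd.read_csv(results)
        else:
            df = results.copy()
        problems = []
        expected = {c.id for c in record.population}
        if "condition_id" not in df.columns:
            problems.append("missing column 'condition_id'")
        else:
            got = set(df["condition_id"].astype(str))
            unknown = sorted(got - expected)
            absent = sorted(expected - got)
            if unknown:
                problems.append(f"unknown condition ids {unknown}")
            if absent:
                problems.append(f"no rows for condition ids {absent}")
        for col in ["replicate"] + self.space.objective_names:
            if col not in df.columns:
                problems.append(f"missing column {col!r}")
            else:
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = df[col].notna() & coerced.isna()
                if bad.any():
                    problems.append(
                        f"non-numeric values in column {col!r}: "
                        f"{df.loc[bad, col].tolist()[:5]}"
                    )
                else:
                    df[col] = coerced
        if problems:
            raise DataError("results rejected: " + "; ".join(problems))
        table = MeasurementTable.from_dataframe(
            record.generation_index, df, self.space.objective_names
        )
        aggregated = aggregate_replicates(table)  # raises on unrepairable cells
        fitness = evaluate_fitness(self.space, aggregated, sorted(expected))
        # validation passed: commit
        record.measurements = table
        record.aggregated = aggregated
        record.fitness = fitness
        self._log("ingest", record.generation_index, {"rows": int(len(df))})
        self.save()
        return fitness

    def step(self) -> dict:
        """Breed the next generation and report convergence metrics.

        Returns the advisory report: score trajectories, better-fraction RSD
        and, from the second ingested generation on, the one-sided Welch
        p-value for improvement of the better fraction (practice: keep going
        while p < 0.05; consider stopping once p > 0.1).
        """
        if self.current.fitness is None:
            raise StateError("ingest results first: no fitness for this generation")
        report = self.convergence_report()
        gen_seed = derived_seed(self.seed, self.current.generation_index + 1)
        record = next_generation(
            self.current, self.params, np.random.default_rng(gen_seed)
        )
        record.seed = gen_seed
        self.history.append(record)
        self._log("step", record.generation_index, {"gen_seed": gen_seed})
        self.save()
        return report

    def convergence_report(self, fraction: float = 0.5) -> dict:
        scored = [g for g in self.history if g.fitness is not None]
        report: dict = {
            "trajectories": score_trajectories(scored, fraction),
            "rsd_better_fraction": [
                relative_standard_deviation(better_fraction_scores(g, fraction))
                for g in scored
            ],
        }
        if len(scored) >= 2:
            report["improvement_p"] = improvement_test(
                better_fraction_scores(scored[-2], fraction),
                better_fraction_scores(scored[-1], fraction),
            )
        return report

    def dataset(self) -> pd.DataFrame:
        """Modelling table over all ingested generations (for SR fitting)."""
        return history_dataset(self.space, self.history)


# ------------------------------------------------------------ serialisation


def _record_to_json(rec: GenerationRecord) -> dict:
    out: dict = {
        "generation_index": rec.generation_index,
        "population": [{"id": c.id, "bits": c.to_string()} for c in rec.population],
        "seed": rec.seed,
        "measurements": None,
        "fitness": None,
    }
    if rec.measurements is not None:
        out["measurements"] = [
            {"condition_id": cid, "replicate": rep,
             "values": {k: (None if v != v else v) for k, v in vals.items()}}
            for cid, rep, vals in rec.measurements.rows
        ]
    if rec.fitness is not None:
        out["fitness"] = {
            "terms": rec.fitness.terms,
            "totals": rec.fitness.totals,
        }
        out["aggregated"] = {
            f"{cid}\t{obj}": v for (cid, obj), v in rec.aggregated.items()
        }
    return out


def _record_from_json(obj: dict) -> GenerationRecord:
    rec = GenerationRecord(
        generation_index=int(obj["generation_index"]),
        population=[
            Chromosome.from_string(c["bits"], c["id"]) for c in obj["population"]
        ],
        seed=obj.get("seed"),
    )
    if obj.get("measurements") is not None:
        rec.measurements = MeasurementTable(
            rec.generation_index,
            [
                (
                    m["condition_id"],
                    int(m["replicate"]),
                    {
                        k: (float("nan") if v is None else float(v))
                        for k, v in m["values"].items()
                    },
                )
                for m in obj["measurements"]
            ],
        )
    if obj.get("fitness") is not None:
        rec.fitness = FitnessResult(
            terms={k: dict(v) for k, v in obj["fitness"]["terms"].items()},
            totals=dict(obj["fitness"]["totals"]),
        )
        rec.aggregated = {
            tuple(k.split("\t")): v for k, v in obj["aggregated"].items()
        }
    return rec
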