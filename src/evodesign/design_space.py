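"""Factors, objectives and the bit-string encoding of experimental conditions.

Each experimental factor is discretised onto ``2**bits`` evenly spaced levels
spanning its allowable physical range.  A *chromosome* is the concatenation of
one binary *gene* per factor, in declared factor order, so a design with nine
5-bit factors is a 45-bit string addressing a 32**9 grid of candidate
conditions.  This module owns the bijection between bit strings and physical
condition values; everything downstream (the GA, diagnostics, the oracle)
speaks in terms of these types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

__all__ = [
    "FactorSpec",
    "ObjectiveSpec",
    "DesignSpace",
    "Chromosome",
    "decode_factor",
    "encode_level",
    "decode_chromosome",
    "encode_condition",
    "population_size_rule",
]


def _gray_to_binary(bits: tuple[int, ...]) -> tuple[int, ...]:
    out = [bits[0]]
    for b in bits[1:]:
        out.append(out[-1] ^ b)
    return tuple(out)


def _binary_to_gray(bits: tuple[int, ...]) -> tuple[int, ...]:
    return (bits[0],) + tuple(bits[i - 1] ^ bits[i] for i in range(1, len(bits)))


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor: a named physical quantity with a working range.

    Parameters
    ----------
    name:
        Identifier used in design/results files (e.g. ``"glycerol"``).
    min_value, max_value:
        Bounds of the allowable range, in physical units (``min < max``).
    bits:
        Gene length; the factor is testable at ``2**bits`` evenly spaced
        levels.  Five bits (32 levels) is the conventional default.
    units:
        Free-text unit label, e.g. ``"g/l"``; informational only.
    """

    name: str
    min_value: float
    max_value: float
    bits: int = 5
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("factor name must be non-empty")
        if not self.min_value < self.max_value:
            raise ValueError(
                f"factor {self.name!r}: min_value ({self.min_value}) must be "
                f"strictly below max_value ({self.max_value})"
            )
        if self.bits < 1:
            raise ValueError(f"factor {self.name!r}: bits must be >= 1")

    @property
    def n_levels(self) -> int:
        return 2**self.bits

    @property
    def step(self) -> float:
        """Spacing between adjacent levels."""
        return (self.max_value - self.min_value) / (self.n_levels - 1)

    def level_value(self, k: int) -> float:
        """Physical value of level index ``k`` (0-based)."""
        if not 0 <= k < self.n_levels:
            raise ValueError(f"factor {self.name!r}: level {k} out of range")
        if k == self.n_levels - 1:  # exact endpoint, no float round-off
            return self.max_value
        return self.min_value + k * self.step


@dataclass(frozen=True)
class ObjectiveSpec:
    """One term of the weighted multi-objective fitness function.

    ``direction`` is ``"maximize"`` or ``"minimize"``; minimised responses
    enter the score as ``1 - normalised`` so that a higher score is always
    better.  Weights are normalised to sum to one at design-space load time.
    """

    name: str
    direction: str = "maximize"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize"):
            raise ValueError(
                f"objective {self.name!r}: direction must be 'maximize' or "
                f"'minimize', got {self.direction!r}"
            )
        if not self.weight >= 0:
            raise ValueError(f"objective {self.name!r}: weight must be >= 0")


@dataclass(frozen=True)
class DesignSpace:
    """Ordered factors plus objectives; the immutable frame of a study."""

    factors: tuple[FactorSpec, ...]
    objectives: tuple[ObjectiveSpec, ...]
    gray_code: bool = False

    def __init__(
        self,
        factors: Sequence[FactorSpec],
        objectives: Sequence[ObjectiveSpec],
        gray_code: bool = False,
    ) -> None:
        factors = tuple(factors)
        objectives = tuple(objectives)
        if not factors:
            raise ValueError("design space needs at least one factor")
        if not objectives:
            raise ValueError("design space needs at least one objective")
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate factor names in {names}")
        onames = [o.name for o in objectives]
        if len(set(onames)) != len(onames):
            raise ValueError(f"duplicate objective names in {onames}")
        total_w = sum(o.weight for o in objectives)
        if total_w <= 0:
            raise ValueError("objective weights must not all be zero")
        objectives = tuple(
            ObjectiveSpec(o.name, o.direction, o.weight / total_w) for o in objectives
        )
        object.__setattr__(self, "factors", factors)
        object.__setattr__(self, "objectives", objectives)
        object.__setattr__(self, "gray_code", bool(gray_code))

    @property
    def chromosome_length(self) -> int:
        """Total bit length L = sum of factor gene lengths."""
        return sum(f.bits for f in self.factors)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def objective_names(self) -> list[str]:
        return [o.name for o in self.objectives]

    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"unknown factor {name!r}")

    @property
    def grid_size(self) -> int:
        """Number of distinct representable conditions (full-factorial size)."""
        return math.prod(f.n_levels for f in self.factors)

    def gene_slices(self) -> list[slice]:
        slices, start = [], 0
        for f in self.factors:
            slices.append(slice(start, start + f.bits))
            start += f.bits
        return slices

    def iter_grid(self) -> Iterator[dict[str, float]]:
        """Enumerate every representable condition (use on tiny spaces only)."""
        from itertools import product

        for ks in product(*(range(f.n_levels) for f in self.factors)):
            yield {f.name: f.level_value(k) for f, k in zip(self.factors, ks)}


@dataclass(frozen=True)
class Chromosome:
    """A bit-encoded candidate condition, unique (by id) within a generation."""

    bits: tuple[int, ...]
    id: str

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"chromosome {self.id!r}: bits must be 0/1")

    @classmethod
    def from_string(cls, s: str, id: str) -> "Chromosome":
        return cls(tuple(int(c) for c in s), id)

    def to_string(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __len__(self) -> int:
        return len(self.bits)


def _gene_index(factor: FactorSpec, gene_bits: Sequence[int], gray: bool) -> int:
    bits = tuple(int(b) for b in gene_bits)
    if gray:
        bits = _gray_to_binary(bits)
    k = 0
    for b in bits:
        k = (k << 1) | b
    return k


def decode_factor(
    factor: FactorSpec, gene_bits: Sequence[int], gray_code: bool = False
) -> float:
    """Map a gene's bit vector to the physical level value of its factor.

    The ``2**bits`` gene values index evenly spaced levels:
    ``min + k * (max - min) / (2**bits - 1)`` where ``k`` is the base-2
    integer value of the gene (Gray-decoded first if ``gray_code``).
    """
    if len(gene_bits) != factor.bits:
        raise ValueError(
            f"factor {factor.name!r} expects {factor.bits} bits, "
            f"got {len(gene_bits)}"
        )
    return factor.level_value(_gene_index(factor, gene_bits, gray_code))


def encode_level(
    factor: FactorSpec, value: float, gray_code: bool = False
) -> tuple[int, ...]:
    """Bits of the representable level nearest ``value``; ties round down."""
    if not factor.min_value <= value <= factor.max_value:
        raise ValueError(
            f"value {value} outside range [{factor.min_value}, "
            f"{factor.max_value}] of factor {factor.name!r}"
        )
    pos = (value - factor.min_value) / factor.step
    k = int(math.floor(pos + 0.5))
    # ties (pos exactly halfway) round toward the lower level index
    if k - pos == 0.5:
        k -= 1
    k = min(k, factor.n_levels - 1)
    bits = tuple((k >> i) & 1 for i in reversed(range(factor.bits)))
    if gray_code:
        bits = _binary_to_gray(bits)
    return bits


def decode_chromosome(
    space: DesignSpace, chromosome: Chromosome | Sequence[int]
) -> dict[str, float]:
    """Split a chromosome into genes (declared factor order) and decode each."""
    bits = chromosome.bits if isinstance(chromosome, Chromosome) else tuple(chromosome)
    L = space.chromosome_length
    if len(bits) != L:
        raise ValueError(
            f"chromosome length {len(bits)} != design-space length {L}"
        )
    out: dict[str, float] = {}
    for f, sl in zip(space.factors, space.gene_slices()):
        out[f.name] = decode_factor(f, bits[sl], space.gray_code)
    return out


def chromosome_level_indices(
    space: DesignSpace, chromosome: Chromosome | Sequence[int]
) -> dict[str, int]:
    """Per-factor level index of a chromosome (used by population profiling)."""
    bits = chromosome.bits if isinstance(chromosome, Chromosome) else tuple(chromosome)
    if len(bits) != space.chromosome_length:
        raise ValueError("chromosome length mismatch")
    return {
        f.name: _gene_index(f, bits[sl], space.gray_code)
        for f, sl in zip(space.factors, space.gene_slices())
    }


def encode_condition(
    space: DesignSpace, condition: Mapping[str, float], id: str = ""
) -> Chromosome:
    """Encode a physical condition as a chromosome (nearest grid point)."""
    bits: list[int] = []
    for f in space.factors:
        if f.name not in condition:
            raise ValueError(f"condition missing factor {f.name!r}")
        bits.extend(encode_level(f, condition[f.name], space.gray_code))
    return Chromosome(tuple(bits), id)


def population_size_rule(n_factors: int) -> int:
    """Default population size 2n - 2 for n factors.

    Sits in the upper part of the n..2n band conventionally recommended for
    GA populations; nine factors give the familiar 16-individual default.
    """
    if n_factors < 2:
        raise ValueError(
            f"population_size_rule needs >= 2 factors, got {n_factors}"
        )
    return 2 * n_factors - 2
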