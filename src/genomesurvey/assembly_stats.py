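"""Assembly continuity/completeness arithmetic and the gene-model filter.

Nx statistics follow the standard convention: sort lengths descending and
report the length at which the cumulative sum first reaches x% of the
total. Printed percentages are reproduced with half-up decimal rounding
(never banker's). The Kosambi mapping function converts a recombination
fraction to centiMorgans accounting for crossover interference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._round import round_half_up

__all__ = [
    "AssemblyMetrics",
    "GeneModelRecord",
    "nx",
    "count_above",
    "percent_ratio",
    "kosambi_cm",
    "filter_gene_models",
]


def nx(lengths: Sequence[int], x: float) -> int:
    """Nx length: sort descending, return the length where the cumulative
    sum first reaches x% of the total."""
    if not lengths:
        raise ValueError("empty length list")
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    ordered = sorted(lengths, reverse=True)
    threshold = x / 100 * sum(ordered)
    cumulative = 0
    for length in ordered:
        cumulative += length
        if cumulative >= threshold:
            return length
    return ordered[-1]  # unreachable barring float slack


def count_above(lengths: Iterable[int], threshold: int) -> int:
    """Number of lengths >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return sum(1 for length in lengths if length >= threshold)


def percent_ratio(numerator, denominator, decimals: int = 2) -> float:
    """100 x numerator / denominator, half-up rounded to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100 * numerator, denominator, decimals)


def kosambi_cm(r: float) -> float:
    """Kosambi map distance in centiMorgans: 25 ln((1 + 2r) / (1 - 2r))."""
    if not 0.0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


@dataclass
class GeneModelRecord:
    """Inputs of the gene-model post-filter."""

    id: str
    cds_length: int
    ab_initio_only: bool
    has_only_uniref_hit: bool
    fpkm: float

    def __post_init__(self) -> None:
        if self.cds_length < 0:
            raise ValueError("cds_length must be non-negative")
        if self.fpkm < 0:
            raise ValueError("fpkm must be non-negative")


def filter_gene_models(
    records: Sequence[GeneModelRecord],
    min_cds: int = 150,
    min_fpkm: float = 5.0,
) -> list[GeneModelRecord]:
    """Apply the two post-prediction removal rules, preserving order.

    A model is removed if its coding region is shorter than ``min_cds``
    bp, or if it is supported by ab initio prediction only, hits nothing
    beyond UniRef, and has FPKM below ``min_fpkm``. The two rules are
    independent; the expression rule never touches models with other
    evidence.
    """
    kept = []
    for rec in records:
        if rec.cds_length < min_cds:
            continue
        if rec.ab_initio_only and rec.has_only_uniref_hit and rec.fpkm < min_fpkm:
            continue
        kept.append(rec)
    return kept


@dataclass
class AssemblyMetrics:
    """Continuity statistics of one scaffold/contig length collection."""

    lengths: list[int]
    total_length: int
    n50: int
    n90: int
    largest: int
    count: int
    count_above_n90: int

    @classmethod
    def from_lengths(cls, lengths: Sequence[int]) -> "AssemblyMetrics":
        if not lengths:
            raise ValueError("empty length list")
        if any(length <= 0 for length in lengths):
            raise ValueError("sequence lengths must be positive")
        n90_val = nx(lengths, 90)
        return cls(
            lengths=list(lengths),
            total_length=sum(lengths),
            n50=nx(lengths, 50),
            n90=n90_val,
            largest=max(lengths),
            count=len(lengths),
            count_above_n90=count_above(lengths, n90_val),
        )

    def as_dict(self) -> dict:
        return {
            "total_length": self.total_length,
            "count": self.count,
            "largest": self.largest,
            "n50": self.n50,
            "n90": self.n90,
            "count_above_n90": self.count_above_n90,
        }
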