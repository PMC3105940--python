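"""Single-pass per-position quality aggregation and coverage arithmetic.

All statistics are kept exact: read means are :class:`fractions.Fraction`,
medians are integers or half-integers, and coverage uses pure integer
arithmetic with truncation (never rounding).  Memory of the aggregate is
bounded by the read length times the number of distinct quality values,
independent of how many reads are streamed through it.
"""

from __future__ import annotations

import math
import os
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .io import QualityRead

__all__ = [
    "read_mean",
    "read_median",
    "PerBaseAggregate",
    "accumulate",
    "per_base_mean_series",
    "base_quality_histogram",
    "CoverageParams",
    "estimate_coverage",
    "coverage_table",
    "retention_percentage",
    "truncate2",
]

Number = int | float | Fraction


def _as_fraction(x: Number) -> Fraction:
    # str() round-trips floats through their shortest repr, so a threshold
    # typed as 19.5 compares as 19.5 exactly, not its binary neighbour
    return x if isinstance(x, Fraction) else Fraction(str(x))


def read_mean(qvs: Sequence[int]) -> Fraction:
    """Exact arithmetic mean of a read's quality values."""
    if not qvs:
        raise ValueError("read_mean of an empty quality vector")
    return Fraction(sum(qvs), len(qvs))


def read_median(qvs: Sequence[int]) -> Fraction:
    """Median: middle value (odd length) or mean of the two middles (even)."""
    if not qvs:
        raise ValueError("read_median of an empty quality vector")
    ordered = sorted(qvs)
    n = len(ordered)
    mid = n // 2
    if n % 2:
        return Fraction(ordered[mid])
    return Fraction(ordered[mid - 1] + ordered[mid], 2)


def truncate2(x: Number) -> float:
    """Truncate toward minus infinity to 2 decimal places."""
    return math.floor(_as_fraction(x) * 100) / 100


@dataclass
class PerBaseAggregate:
    """Frequency tables of quality values per position plus per-read stats.

    ``position_freq`` is indexed 0-based internally; user-facing accessors
    take 1-based positions.  ``read_mean_freq``/``read_median_freq`` are
    keyed by the exact statistic (Fraction); :meth:`mean_freq_2dp` exposes
    the 2-decimal-truncated view used for table export.
    """

    read_length: int
    n_reads: int = 0
    position_freq: list[Counter] = field(default_factory=list)
    read_mean_freq: Counter = field(default_factory=Counter)
    read_median_freq: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not self.position_freq:
            self.position_freq = [Counter() for _ in range(self.read_length)]

    def add(self, read: QualityRead) -> None:
        if len(read.qvs) != self.read_length:
            raise ValueError(
                f"read {read.record_id!r} has {len(read.qvs)} values, "
                f"expected {self.read_length}"
            )
        for counter, qv in zip(self.position_freq, read.qvs):
            counter[qv] += 1
        self.read_mean_freq[read_mean(read.qvs)] += 1
        self.read_median_freq[read_median(read.qvs)] += 1
        self.n_reads += 1

    def mean_freq_2dp(self) -> Counter:
        """Read-mean frequencies with keys truncated to 2 decimals."""
        out: Counter = Counter()
        for mean, count in self.read_mean_freq.items():
            out[truncate2(mean)] += count
        return out

    def check_invariants(self) -> None:
        for p, counter in enumerate(self.position_freq, start=1):
            if sum(counter.values()) != self.n_reads:
                raise AssertionError(f"position {p} counts do not sum to n_reads")
        for name, freq in (("mean", self.read_mean_freq), ("median", self.read_median_freq)):
            if sum(freq.values()) != self.n_reads:
                raise AssertionError(f"read_{name}_freq does not sum to n_reads")

    def write_position_tsv(self, path: str | os.PathLike) -> None:
        """Export (position, qv, count) rows, positions 1-based."""
        with open(path, "w") as fh:
            fh.write("position\tqv\tcount\n")
            for p, counter in enumerate(self.position_freq, start=1):
                for qv in sorted(counter):
                    fh.write(f"{p}\t{qv}\t{counter[qv]}\n")

    def write_read_stat_tsv(self, path: str | os.PathLike) -> None:
        """Export (statistic, value, count) rows; means truncated to 2 dp."""
        with open(path, "w") as fh:
            fh.write("statistic\tvalue\tcount\n")
            mean2 = self.mean_freq_2dp()
            for value in sorted(mean2):
                fh.write(f"mean\t{value:.2f}\t{mean2[value]}\n")
            for value in sorted(self.read_median_freq):
                fh.write(f"median\t{float(value):g}\t{self.read_median_freq[value]}\n")


def accumulate(reads: Iterable[QualityRead], read_length: int) -> PerBaseAggregate:
    """Fold a stream of equal-length reads into a :class:`PerBaseAggregate`."""
    agg = PerBaseAggregate(read_length)
    for read in reads:
        agg.add(read)
    return agg


def per_base_mean_series(agg: PerBaseAggregate) -> list[Fraction]:
    """Mean quality per position (1..L order), exact."""
    if agg.n_reads == 0:
        raise ValueError("per_base_mean_series of an empty aggregate")
    return [
        Fraction(sum(qv * count for qv, count in counter.items()), agg.n_reads)
        for counter in agg.position_freq
    ]


def base_quality_histogram(agg: PerBaseAggregate, position: int) -> dict[int, int]:
    """Quality-value frequencies at a 1-based position (copied)."""
    if not 1 <= position <= agg.read_length:
        raise ValueError(f"position {position} out of range 1..{agg.read_length}")
    return dict(agg.position_freq[position - 1])


@dataclass(frozen=True)
class CoverageParams:
    """Inputs of the coverage estimate: reads n, read length L, genome size S."""

    n: int
    L: int
    S: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("read count must be >= 0")
        if self.L < 1:
            raise ValueError("read length must be >= 1")
        if self.S < 1:
            raise ValueError("genome size must be >= 1")


def estimate_coverage(params: CoverageParams) -> int:
    """Fold coverage floor((n * L) / S), exact integer arithmetic."""
    return (params.n * params.L) // params.S


def coverage_table(
    agg: PerBaseAggregate,
    thresholds: Sequence[Number],
    L: int,
    S: int,
) -> dict[tuple[str, Number], tuple[int, int]]:
    """Kept-read counts and coverage per (statistic, threshold) cell.

    Computed from the aggregate's read-statistic frequency maps alone — no
    re-scan of the reads.  A read is kept when its statistic is >= the
    threshold (inclusive boundary).
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    table: dict[tuple[str, Number], tuple[int, int]] = {}
    freqs: dict[str, Mapping[Fraction, int]] = {
        "mean": agg.read_mean_freq,
        "median": agg.read_median_freq,
    }
    for statistic, freq in freqs.items():
        for t in thresholds:
            cutoff = _as_fraction(t)
            kept = sum(count for value, count in freq.items() if value >= cutoff)
            table[(statistic, t)] = (kept, estimate_coverage(CoverageParams(kept, L, S)))
    return table


def retention_percentage(kept: int, raw: int) -> float:
    """Percent of reads retained, truncated (not rounded) to 2 decimals."""
    if raw < 1:
        raise ValueError("raw read count must be >= 1")
    if not 0 <= kept <= raw:
        raise ValueError("kept must be in [0, raw]")
    return (10000 * kept // raw) / 100
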