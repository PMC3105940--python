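"""Mean/median phred-cutoff filtering of paired quality/sequence streams.

A read is retained iff its chosen statistic (exact, unrounded) is greater
than or equal to the threshold.  Format-rejected records never appear in
the discard count: validation eliminations live in the ValidationLog,
quality rejections in the FilterOutcome, so raw/kept/discarded accounting
stays reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable, Iterator

from . import io as qio
from .io import Encoding, QualityRead, ReadPair, ValidationLog
from .stats import read_mean, read_median, retention_percentage

__all__ = [
    "FilterConfig",
    "FilterOutcome",
    "filter_pairs",
    "filter_quality_reads",
    "run_filter_job",
]

_STATISTICS: dict[str, Callable[[tuple[int, ...]], Fraction]] = {
    "mean": read_mean,
    "median": read_median,
}


@dataclass(frozen=True)
class FilterConfig:
    """Which per-read statistic to threshold, and at what phred value."""

    statistic: str
    threshold: int | float | Fraction

    def __post_init__(self) -> None:
        if self.statistic not in _STATISTICS:
            raise ValueError(f"statistic must be one of {sorted(_STATISTICS)}")
        if self.threshold < -1:
            raise ValueError("threshold must be >= -1")

    def keeps(self, qvs: tuple[int, ...]) -> bool:
        cutoff = self.threshold
        if isinstance(cutoff, float):
            cutoff = Fraction(str(cutoff))
        return _STATISTICS[self.statistic](qvs) >= cutoff


@dataclass
class FilterOutcome:
    """Counts and output paths of one filtering run."""

    raw_count: int = 0
    kept_count: int = 0
    discarded_count: int = 0
    qual_output: str | None = None
    seq_output: str | None = None

    @property
    def retention_percent(self) -> float:
        if self.raw_count == 0:
            return 0.0
        return retention_percentage(self.kept_count, self.raw_count)

    def as_dict(self) -> dict:
        return {
            "raw": self.raw_count,
            "kept": self.kept_count,
            "discarded": self.discarded_count,
            "retention_percent": self.retention_percent,
            "outputs": [p for p in (self.qual_output, self.seq_output) if p],
        }

    def write_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)
            fh.write("\n")

    def write_report(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"raw: {self.raw_count}\n")
            fh.write(f"kept: {self.kept_count}\n")
            fh.write(f"discarded: {self.discarded_count}\n")
            fh.write(f"retention_percent: {self.retention_percent:.2f}\n")


def filter_pairs(
    pairs: Iterable[ReadPair], cfg: FilterConfig
) -> tuple[Iterator[ReadPair], FilterOutcome]:
    """Lazily retain pairs whose quality statistic meets the cutoff.

    The outcome's counts are final only once the iterator is exhausted.
    """
    outcome = FilterOutcome()

    def gen() -> Iterator[ReadPair]:
        for pair in pairs:
            outcome.raw_count += 1
            if cfg.keeps(pair.qual.qvs):
                outcome.kept_count += 1
                yield pair
            else:
                outcome.discarded_count += 1

    return gen(), outcome


def filter_quality_reads(
    reads: Iterable[QualityRead], cfg: FilterConfig
) -> tuple[Iterator[QualityRead], FilterOutcome]:
    """Quality-only variant of :func:`filter_pairs`."""
    outcome = FilterOutcome()

    def gen() -> Iterator[QualityRead]:
        for read in reads:
            outcome.raw_count += 1
            if cfg.keeps(read.qvs):
                outcome.kept_count += 1
                yield read
            else:
                outcome.discarded_count += 1

    return gen(), outcome


def run_filter_job(
    qual_path: str | os.PathLike,
    seq_path: str | os.PathLike | None,
    expected_length: int,
    cfg: FilterConfig,
    *,
    encoding: Encoding | None = None,
) -> tuple[FilterOutcome, ValidationLog]:
    """Parse, pair, filter and write ``.new`` files in one streaming pass.

    When ``seq_path`` is None the job runs quality-only and emits a single
    filtered quality file.  Outcome counts cover successfully paired
    records only; parser and pairing eliminations are reported in the
    returned log.
    """
    qual_path = os.fspath(qual_path)
    log = ValidationLog()
    if seq_path is None:
        with open(qual_path) as qfh:
            quals, qlog = qio.parse_quality_file(
                qfh, expected_length, source=os.path.basename(qual_path)
            )
            retained, outcome = filter_quality_reads(quals, cfg)
            outcome.qual_output = qio.write_quality_file(retained, qio.filtered_name(qual_path))
        log.extend(qlog)
        return outcome, log

    seq_path = os.fspath(seq_path)
    if encoding is None:
        encoding = qio.sniff_file_encoding(seq_path)
    with open(qual_path) as qfh, open(seq_path) as sfh:
        quals, qlog = qio.parse_quality_file(
            qfh, expected_length, source=os.path.basename(qual_path)
        )
        seqs, slog = qio.parse_sequence_file(
            sfh, expected_length, encoding, source=os.path.basename(seq_path)
        )
        pairs, plog = qio.pair_records(quals, seqs)
        retained, outcome = filter_pairs(pairs, cfg)
        outcome.qual_output, outcome.seq_output = qio.write_filtered_pair(
            retained, qual_path, seq_path
        )
    for part in (qlog, slog, plog):
        log.extend(part)
    return outcome, log
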