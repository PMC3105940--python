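"""Streaming readers and writers for read-quality and sequence files.

Two multifasta-style dialects are handled:

* quality files — a ``>`` header per read followed by one or more lines of
  whitespace-separated integer phred values (SOLiD ``.qual`` convention;
  values for one record may span multiple lines);
* sequence files — nucleotide FASTA or SOLiD color-space ``.csfasta``
  (primer base followed by digits ``0-3`` and ``.`` for missed calls).

Records failing validation are eliminated, never fatal: every elimination
and every skipped line lands in a :class:`ValidationLog` with a
machine-readable reason code.  Parsers are strictly single-pass.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "Encoding",
    "Reason",
    "LogEntry",
    "ValidationLog",
    "QualityRead",
    "SequenceRead",
    "ReadPair",
    "parse_quality_file",
    "parse_sequence_file",
    "detect_encoding",
    "pair_records",
    "write_quality_file",
    "write_sequence_file",
    "write_filtered_pair",
    "filtered_name",
    "QV_MIN",
    "QV_MAX",
]

QV_MIN = -1  # SOLiD missed-call sentinel
QV_MAX = 93

_NUCLEOTIDES = frozenset("ACGTN")
_PRIMER_BASES = frozenset("ACGT")
_COLORS = frozenset("0123.")

#: suffix appended to every emitted filtered file
FILTERED_SUFFIX = ".new"


class Encoding(str, Enum):
    """Sequence alphabet of a read file."""

    NUCLEOTIDE = "nucleotide"
    COLORSPACE = "colorspace"


class Reason(str, Enum):
    """Why a record or line was eliminated/skipped during parsing."""

    WRONG_LENGTH = "WRONG_LENGTH"
    INVALID_CHARACTER = "INVALID_CHARACTER"
    BLANK_LINE = "BLANK_LINE"
    MALFORMED_HEADER = "MALFORMED_HEADER"
    NON_INTEGER_QV = "NON_INTEGER_QV"
    QV_OUT_OF_RANGE = "QV_OUT_OF_RANGE"
    UNPAIRED_RECORD = "UNPAIRED_RECORD"


#: reasons that eliminate a whole record (as opposed to merely skipping a line)
ELIMINATION_REASONS = frozenset(
    {
        Reason.WRONG_LENGTH,
        Reason.INVALID_CHARACTER,
        Reason.NON_INTEGER_QV,
        Reason.QV_OUT_OF_RANGE,
    }
)


@dataclass(frozen=True)
class LogEntry:
    source_file: str
    line_number: int
    record_id: str
    reason: Reason

    def as_tsv(self) -> str:
        return f"{self.source_file}\t{self.line_number}\t{self.record_id}\t{self.reason.value}"


@dataclass
class ValidationLog:
    """Ordered account of every eliminated record and skipped line."""

    entries: list[LogEntry] = field(default_factory=list)

    def add(self, source_file: str, line_number: int, record_id: str, reason: Reason) -> None:
        self.entries.append(LogEntry(source_file, line_number, record_id, reason))

    def extend(self, other: "ValidationLog") -> None:
        self.entries.extend(other.entries)

    def count(self, *reasons: Reason) -> int:
        wanted = set(reasons) if reasons else None
        return sum(1 for e in self.entries if wanted is None or e.reason in wanted)

    def eliminated(self) -> int:
        """Number of whole records eliminated (blank lines etc. excluded)."""
        return self.count(*ELIMINATION_REASONS)

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("file\tline\tid\treason\n")
            for entry in self.entries:
                fh.write(entry.as_tsv() + "\n")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LogEntry]:
        return iter(self.entries)

    def __bool__(self) -> bool:
        return bool(self.entries)


@dataclass(frozen=True)
class QualityRead:
    """One read's ordered phred values (integers in [-1, 93])."""

    record_id: str
    qvs: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.qvs)


@dataclass(frozen=True)
class SequenceRead:
    """One read's symbols: plain nucleotides, or primer base + colors."""

    record_id: str
    symbols: str
    encoding: Encoding

    def n_positions(self) -> int:
        """Number of called positions (colors exclude the primer base)."""
        if self.encoding is Encoding.COLORSPACE:
            return len(self.symbols) - 1
        return len(self.symbols)


@dataclass(frozen=True)
class ReadPair:
    record_id: str
    seq: SequenceRead
    qual: QualityRead


def _header_id(line: str) -> str:
    return line[1:].split()[0] if line[1:].split() else ""


def parse_quality_file(
    stream: IO[str] | Iterable[str],
    expected_length: int,
    *,
    source: str = "<stream>",
) -> tuple[Iterator[QualityRead], ValidationLog]:
    """Stream quality records, eliminating malformed ones into the log.

    Returns a lazy iterator plus the log it fills while being consumed.
    Exactly one elimination entry is recorded per rejected record, checked
    in the order NON_INTEGER_QV, QV_OUT_OF_RANGE, WRONG_LENGTH.
    """
    if expected_length < 1:
        raise ValueError("expected_length must be >= 1")
    log = ValidationLog()
    return _iter_quality(stream, expected_length, source, log), log


def _iter_quality(
    stream: Iterable[str], expected_length: int, source: str, log: ValidationLog
) -> Iterator[QualityRead]:
    record_id: str | None = None
    header_line = 0
    tokens: list[str] = []

    def finish() -> QualityRead | None:
        if record_id is None:
            return None
        qvs: list[int] = []
        for tok in tokens:
            try:
                qvs.append(int(tok))
            except ValueError:
                log.add(source, header_line, record_id, Reason.NON_INTEGER_QV)
                return None
        if any(q < QV_MIN or q > QV_MAX for q in qvs):
            log.add(source, header_line, record_id, Reason.QV_OUT_OF_RANGE)
            return None
        if len(qvs) != expected_length:
            log.add(source, header_line, record_id, Reason.WRONG_LENGTH)
            return None
        return QualityRead(record_id, tuple(qvs))

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            log.add(source, lineno, record_id or "", Reason.BLANK_LINE)
            continue
        if line.startswith(">"):
            read = finish()
            if read is not None:
                yield read
            record_id = _header_id(line)
            header_line = lineno
            tokens = []
        elif record_id is None:
            log.add(source, lineno, "", Reason.MALFORMED_HEADER)
        else:
            tokens.extend(line.split())
    read = finish()
    if read is not None:
        yield read


def parse_sequence_file(
    stream: IO[str] | Iterable[str],
    expected_length: int,
    encoding: Encoding,
    *,
    source: str = "<stream>",
) -> tuple[Iterator[SequenceRead], ValidationLog]:
    """Stream sequence records (nucleotide or color space) with elimination.

    ``expected_length`` counts called positions: a color-space record must
    carry a primer base plus exactly that many color symbols.
    """
    if expected_length < 1:
        raise ValueError("expected_length must be >= 1")
    encoding = Encoding(encoding)
    log = ValidationLog()
    return _iter_sequence(stream, expected_length, encoding, source, log), log


def _iter_sequence(
    stream: Iterable[str],
    expected_length: int,
    encoding: Encoding,
    source: str,
    log: ValidationLog,
) -> Iterator[SequenceRead]:
    record_id: str | None = None
    header_line = 0
    chunks: list[str] = []

    def finish() -> SequenceRead | None:
        if record_id is None:
            return None
        symbols = "".join(chunks)
        if encoding is Encoding.NUCLEOTIDE:
            symbols = symbols.upper()
            if not set(symbols) <= _NUCLEOTIDES:
                log.add(source, header_line, record_id, Reason.INVALID_CHARACTER)
                return None
            if len(symbols) != expected_length:
                log.add(source, header_line, record_id, Reason.WRONG_LENGTH)
                return None
        else:
            if symbols:
                symbols = symbols[0].upper() + symbols[1:]
            if not symbols or symbols[0] not in _PRIMER_BASES or not set(symbols[1:]) <= _COLORS:
                log.add(source, header_line, record_id, Reason.INVALID_CHARACTER)
                return None
            if len(symbols) - 1 != expected_length:
                log.add(source, header_line, record_id, Reason.WRONG_LENGTH)
                return None
        return SequenceRead(record_id, symbols, encoding)

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            log.add(source, lineno, record_id or "", Reason.BLANK_LINE)
            continue
        if line.startswith(">"):
            read = finish()
            if read is not None:
                yield read
            record_id = _header_id(line)
            header_line = lineno
            chunks = []
        elif record_id is None:
            log.add(source, lineno, "", Reason.MALFORMED_HEADER)
        else:
            chunks.append(line.strip())
    read = finish()
    if read is not None:
        yield read


def detect_encoding(first_record_symbols: str) -> Encoding:
    """Classify a symbol string as color space or nucleotide.

    Color space requires a primer base followed by at least one color
    symbol; everything else (including a single base) is nucleotide.
    """
    if not first_record_symbols:
        raise ValueError("cannot detect encoding of an empty symbol string")
    s = first_record_symbols.upper()
    if len(s) >= 2 and s[0] in _PRIMER_BASES and set(s[1:]) <= _COLORS:
        return Encoding.COLORSPACE
    return Encoding.NUCLEOTIDE


def sniff_file_encoding(path: str | os.PathLike) -> Encoding:
    """Detect the encoding of a sequence file from its first record."""
    with open(path) as fh:
        chunks: list[str] = []
        seen_header = False
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if seen_header and chunks:
                    break
                seen_header = True
                continue
            if seen_header:
                chunks.append(line)
    if not chunks:
        raise ValueError(f"no sequence records found in {path}")
    return detect_encoding("".join(chunks))


def pair_records(
    quals: Iterable[QualityRead],
    seqs: Iterable[SequenceRead],
    *,
    source: str = "<pairing>",
) -> tuple[Iterator[ReadPair], ValidationLog]:
    """Pair records positionally, verifying ids.

    A positional pair with differing ids drops both records under a single
    UNPAIRED_RECORD entry; trailing records on either side are dropped and
    logged one entry each.  The log's line numbers are 1-based positional
    indices, not file lines.
    """
    log = ValidationLog()
    return _iter_pairs(quals, seqs, source, log), log


def _iter_pairs(
    quals: Iterable[QualityRead],
    seqs: Iterable[SequenceRead],
    source: str,
    log: ValidationLog,
) -> Iterator[ReadPair]:
    qit, sit = iter(quals), iter(seqs)
    index = 0
    while True:
        q = next(qit, None)
        s = next(sit, None)
        index += 1
        if q is None and s is None:
            return
        if q is None or s is None:
            leftover = q if q is not None else s
            log.add(source, index, leftover.record_id, Reason.UNPAIRED_RECORD)
            remaining = qit if q is not None else sit
            for extra in remaining:
                index += 1
                log.add(source, index, extra.record_id, Reason.UNPAIRED_RECORD)
            return
        if q.record_id != s.record_id:
            log.add(source, index, f"{q.record_id}|{s.record_id}", Reason.UNPAIRED_RECORD)
            continue
        yield ReadPair(q.record_id, s, q)


def _format_quality(read: QualityRead) -> str:
    return f">{read.record_id}\n" + " ".join(str(q) for q in read.qvs) + "\n"


def _format_sequence(read: SequenceRead) -> str:
    return f">{read.record_id}\n{read.symbols}\n"


def write_quality_file(reads: Iterable[QualityRead], path: str | os.PathLike) -> str:
    path = os.fspath(path)
    with open(path, "w") as fh:
        for read in reads:
            fh.write(_format_quality(read))
    return path


def write_sequence_file(reads: Iterable[SequenceRead], path: str | os.PathLike) -> str:
    path = os.fspath(path)
    with open(path, "w") as fh:
        for read in reads:
            fh.write(_format_sequence(read))
    return path


def filtered_name(path: str | os.PathLike) -> str:
    """Output name for a filtered file: original name + ``.new``."""
    return os.fspath(path) + FILTERED_SUFFIX


def write_filtered_pair(
    pairs: Iterable[ReadPair],
    qual_path: str | os.PathLike,
    seq_path: str | os.PathLike,
) -> tuple[str, str]:
    """Write retained pairs next to the originals with a ``.new`` suffix.

    On any I/O failure both partial outputs are removed before the error
    propagates.
    """
    out_qual = filtered_name(qual_path)
    out_seq = filtered_name(seq_path)
    try:
        with open(out_qual, "w") as qfh, open(out_seq, "w") as sfh:
            for pair in pairs:
                qfh.write(_format_quality(pair.qual))
                sfh.write(_format_sequence(pair.seq))
    except BaseException:
        for p in (out_qual, out_seq):
            if os.path.exists(p):
                os.remove(p)
        raise
    return out_qual, out_seq
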