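"""Deterministic synthetic paired qual/sequence datasets with ground truth.

The generator writes a quality file, a matching sequence file (nucleotide
FASTA or color-space csfasta) and a tab-separated truth manifest holding
every read's exact quality vector, mean, median and corruption status.
Randomness comes from :class:`random.Random` (Mersenne Twister — stable
across platforms), so identical seeds give byte-identical files.

Corruption modes cover the parser's elimination paths one-for-one:

``wrong_length``
    quality record short one value; sequence record short one symbol.
``invalid_character``
    sequence record carries an illegal symbol; the matching quality
    record is truncated so both files eliminate the same read and the
    positional pairing stays aligned.
``non_integer_qv``
    a quality token replaced by text; sequence truncated for the same
    alignment reason.
``blank_line``
    a blank line inserted inside the record — logged by the parser but
    the read survives, so it is not flagged as eliminated.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from .io import Encoding
from .stats import read_mean, read_median

__all__ = [
    "QualityProfile",
    "DatasetPaths",
    "ManifestRow",
    "generate_dataset",
    "read_manifest",
    "paper_shape_profile",
    "uniform_profile",
    "expected_position_means",
    "CORRUPTION_KINDS",
]

CORRUPTION_KINDS = ("wrong_length", "invalid_character", "non_integer_qv", "blank_line")

#: corruption kinds that cause the parser to eliminate the read
ELIMINATING_KINDS = frozenset({"wrong_length", "invalid_character", "non_integer_qv"})


@dataclass(frozen=True)
class QualityProfile:
    """Per-position quality-value distributions for synthetic reads."""

    length: int
    position_dists: tuple[dict[int, float], ...]
    fraction_malformed: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if len(self.position_dists) != self.length:
            raise ValueError("need one distribution per position")
        for p, dist in enumerate(self.position_dists, start=1):
            if not dist:
                raise ValueError(f"empty distribution at position {p}")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities at position {p} sum to {total}, not 1")
        if not 0.0 <= self.fraction_malformed <= 1.0:
            raise ValueError("fraction_malformed must be in [0, 1]")


@dataclass(frozen=True)
class DatasetPaths:
    qual_path: str
    seq_path: str
    manifest_path: str


@dataclass(frozen=True)
class ManifestRow:
    record_id: str
    qvs: tuple[int, ...]
    mean: Fraction
    median: Fraction
    corrupted: bool  # True iff the parser will eliminate this read
    corruption_kind: str  # empty when the read is pristine


def uniform_profile(
    length: int,
    dist: dict[int, float],
    *,
    fraction_malformed: float = 0.0,
    seed: int = 0,
) -> QualityProfile:
    """Profile with the same quality distribution at every position."""
    return QualityProfile(
        length=length,
        position_dists=tuple(dict(dist) for _ in range(length)),
        fraction_malformed=fraction_malformed,
        seed=seed,
    )


def paper_shape_profile(*, fraction_malformed: float = 0.0, seed: int = 0) -> QualityProfile:
    """Canned 35-base profile echoing a typical short-read quality shape.

    Exactly 17 interior positions have an expected mean quality >= 20;
    the flanks — especially the terminal base, whose modal value is
    phred 5 — fall below 20.
    """
    good = {23: 0.8, 12: 0.2}  # E = 20.8
    poor = {18: 0.6, 15: 0.4}  # E = 16.8
    last = {5: 0.6, 26: 0.4}  # E = 13.4, mode at 5
    dists: list[dict[int, float]] = []
    for pos in range(35):
        if pos == 34:
            dists.append(dict(last))
        elif 9 <= pos <= 25:
            dists.append(dict(good))
        else:
            dists.append(dict(poor))
    return QualityProfile(
        length=35,
        position_dists=tuple(dists),
        fraction_malformed=fraction_malformed,
        seed=seed,
    )


def expected_position_means(profile: QualityProfile) -> list[float]:
    """Analytic expected mean quality at each position."""
    return [
        sum(qv * p for qv, p in dist.items())
        for dist in profile.position_dists
    ]


def _sample_qvs(profile: QualityProfile, rng: random.Random) -> tuple[int, ...]:
    qvs = []
    for dist in profile.position_dists:
        values = sorted(dist)
        weights = [dist[v] for v in values]
        qvs.append(rng.choices(values, weights=weights)[0])
    return tuple(qvs)


def _sample_symbols(length: int, encoding: Encoding, rng: random.Random) -> str:
    if encoding is Encoding.COLORSPACE:
        return rng.choice("ACGT") + "".join(rng.choice("0123") for _ in range(length))
    return "".join(rng.choice("ACGT") for _ in range(length))


def generate_dataset(
    profile: QualityProfile,
    n: int,
    encoding: Encoding | str,
    out_dir: str | os.PathLike,
    *,
    basename: str = "reads",
) -> DatasetPaths:
    """Write n paired records plus a truth manifest; seeded, reproducible."""
    if n < 0:
        raise ValueError("n must be >= 0")
    encoding = Encoding(encoding)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    ext = "csfasta" if encoding is Encoding.COLORSPACE else "fasta"
    qual_path = os.path.join(out_dir, f"{basename}.qual")
    seq_path = os.path.join(out_dir, f"{basename}.{ext}")
    manifest_path = os.path.join(out_dir, f"{basename}.manifest.tsv")

    rng = random.Random(profile.seed)
    kind_cycle = 0
    with open(qual_path, "w") as qfh, open(seq_path, "w") as sfh, open(
        manifest_path, "w"
    ) as mfh:
        mfh.write("record_id\tqvs\tmean\tmedian\tcorrupted\tcorruption_kind\n")
        for i in range(n):
            record_id = f"read_{i:06d}"
            qvs = _sample_qvs(profile, rng)
            symbols = _sample_symbols(profile.length, encoding, rng)
            kind = ""
            if profile.fraction_malformed > 0 and rng.random() < profile.fraction_malformed:
                kind = CORRUPTION_KINDS[kind_cycle % len(CORRUPTION_KINDS)]
                kind_cycle += 1
            _write_record(qfh, sfh, record_id, qvs, symbols, kind, rng)
            mfh.write(
                f"{record_id}\t{','.join(map(str, qvs))}\t{read_mean(qvs)}\t"
                f"{read_median(qvs)}\t{int(kind in ELIMINATING_KINDS)}\t{kind}\n"
            )
    return DatasetPaths(qual_path, seq_path, manifest_path)


def _write_record(
    qfh,
    sfh,
    record_id: str,
    qvs: tuple[int, ...],
    symbols: str,
    kind: str,
    rng: random.Random,
) -> None:
    q_tokens = [str(q) for q in qvs]
    header = f">{record_id}\n"
    if kind == "wrong_length":
        q_tokens = q_tokens[:-1]
        symbols = symbols[:-1]
    elif kind == "invalid_character":
        pos = rng.randrange(1, len(symbols))  # never the color-space primer
        symbols = symbols[:pos] + "X" + symbols[pos + 1 :]
        q_tokens = q_tokens[:-1]  # eliminate the mate too, keeping pairing aligned
    elif kind == "non_integer_qv":
        q_tokens[rng.randrange(len(q_tokens))] = "NA"
        symbols = symbols[:-1]
    qfh.write(header)
    if kind == "blank_line":
        qfh.write("\n")
    qfh.write(" ".join(q_tokens) + "\n")
    sfh.write(header)
    if kind == "blank_line":
        sfh.write("\n")
    sfh.write(symbols + "\n")


def read_manifest(path: str | os.PathLike) -> list[ManifestRow]:
    """Parse a truth manifest back into typed rows."""
    rows: list[ManifestRow] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("record_id\t"):
            raise ValueError(f"not a manifest file: {path}")
        for line in fh:
            record_id, qvs_s, mean_s, median_s, corrupted_s, kind = (
                line.rstrip("\n").split("\t")
            )
            rows.append(
                ManifestRow(
                    record_id=record_id,
                    qvs=tuple(int(t) for t in qvs_s.split(",")),
                    mean=Fraction(mean_s),
                    median=Fraction(median_s),
                    corrupted=bool(int(corrupted_s)),
                    corruption_kind=kind,
                )
            )
    return rows
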