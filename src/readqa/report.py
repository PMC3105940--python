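"""Chart-ready series and static plot rendering.

Series are pure functions of a :class:`~readqa.stats.PerBaseAggregate`;
rendering is presentation-only and deterministic (same series, same SVG
bytes).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .stats import PerBaseAggregate, base_quality_histogram, per_base_mean_series

__all__ = [
    "ChartKind",
    "ChartSeries",
    "mean_per_base_series",
    "position_histogram_series",
    "last_base_histogram_series",
    "read_stat_distribution_series",
    "render",
    "write_series_tsv",
]

# fixed salt + stripped date metadata make SVG output byte-reproducible
_SVG_HASHSALT = "readqa"


class ChartKind(str, Enum):
    PER_BASE_MEAN = "per_base_mean"
    BASE_QV_HISTOGRAM = "base_qv_histogram"
    READ_STAT_DISTRIBUTION = "read_stat_distribution"


@dataclass(frozen=True)
class ChartSeries:
    kind: ChartKind
    x: tuple
    y: tuple
    xlabel: str
    ylabel: str
    title: str

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")


def mean_per_base_series(agg: PerBaseAggregate) -> ChartSeries:
    """Base position (x) against mean base quality (y)."""
    means = per_base_mean_series(agg)
    return ChartSeries(
        kind=ChartKind.PER_BASE_MEAN,
        x=tuple(range(1, agg.read_length + 1)),
        y=tuple(float(m) for m in means),
        xlabel="Base position",
        ylabel="Mean quality (phred)",
        title="Mean quality per base",
    )


def position_histogram_series(agg: PerBaseAggregate, position: int | None = None) -> ChartSeries:
    """Quality value (x) against frequency (y) at one position (default: last)."""
    if agg.n_reads == 0:
        raise ValueError("histogram of an empty aggregate")
    if position is None:
        position = agg.read_length
    hist = base_quality_histogram(agg, position)
    xs = tuple(sorted(hist))
    return ChartSeries(
        kind=ChartKind.BASE_QV_HISTOGRAM,
        x=xs,
        y=tuple(hist[q] for q in xs),
        xlabel="Phred quality value",
        ylabel="Frequency",
        title=f"Quality value frequencies at base {position}",
    )


def last_base_histogram_series(agg: PerBaseAggregate) -> ChartSeries:
    return position_histogram_series(agg, agg.read_length)


def read_stat_distribution_series(agg: PerBaseAggregate, statistic: str) -> ChartSeries:
    """Distribution of per-read means or medians over the dataset."""
    if agg.n_reads == 0:
        raise ValueError("distribution of an empty aggregate")
    if statistic == "mean":
        freq = agg.mean_freq_2dp()
    elif statistic == "median":
        freq = {float(k): v for k, v in agg.read_median_freq.items()}
    else:
        raise ValueError("statistic must be 'mean' or 'median'")
    xs = tuple(sorted(freq))
    return ChartSeries(
        kind=ChartKind.READ_STAT_DISTRIBUTION,
        x=xs,
        y=tuple(freq[v] for v in xs),
        xlabel=f"Read {statistic} quality",
        ylabel="Frequency",
        title=f"Distribution of read {statistic} quality",
    )


def render(series: ChartSeries, path: str | os.PathLike) -> str:
    """Render a series to a static PNG/SVG image file."""
    path = os.fspath(path)
    with plt.rc_context({"svg.hashsalt": _SVG_HASHSALT}):
        fig, ax = plt.subplots(figsize=(8, 4.5))
        try:
            if series.kind is ChartKind.PER_BASE_MEAN:
                ax.plot(series.x, series.y, marker="o", markersize=3)
            else:
                ax.bar(series.x, series.y, width=0.8)
            ax.set_xlabel(series.xlabel)
            ax.set_ylabel(series.ylabel)
            ax.set_title(series.title)
            fig.tight_layout()
            fig.savefig(path, metadata=_image_metadata(path))
        finally:
            plt.close(fig)
    return path


def _image_metadata(path: str) -> dict | None:
    # strip timestamps so identical series render to identical bytes
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": None}
    return None


def write_series_tsv(series: ChartSeries, path: str | os.PathLike) -> str:
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("x\ty\n")
        for x, y in zip(series.x, series.y):
            fh.write(f"{x:g}\t{y:g}\n")
    return path
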