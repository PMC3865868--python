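"""Minimal FastQC-like read metrics: per-base quality, Q30 yield, GC
distribution and configurable red-flag thresholds.

"Average length of read with quality score at 30 or above" is ambiguous,
so both defensible readings are computed and clearly labelled: the mean
number of Q>=30 bases per read, and the percentage of reads whose mean
quality is >= 30.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from knowyourdata.io_formats import ReadRecord
from knowyourdata.matepair import gc_read_histogram

PHRED_OFFSET = 33


def _scores(quality: str) -> np.ndarray:
    return np.frombuffer(quality.encode("ascii"), dtype=np.uint8).astype(np.int32) - PHRED_OFFSET


@dataclass
class PerBaseQuality:
    """Per-cycle phred statistics; cycle positions are 1-based.

    Statistics at each cycle are computed only over reads long enough to
    reach it; length_distribution records how many reads had each length.
    """

    mean: list[float]
    median: list[float]
    q1: list[float]
    q3: list[float]
    coverage: list[int]
    length_distribution: dict[int, int]

    @property
    def max_length(self) -> int:
        return len(self.mean)

    def to_tsv(self, path: str) -> str:
        with open(path, "wt") as handle:
            handle.write("cycle\tmean\tmedian\tq1\tq3\tn\n")
            for i in range(self.max_length):
                handle.write(
                    f"{i + 1}\t{self.mean[i]:.4f}\t{self.median[i]:.4f}"
                    f"\t{self.q1[i]:.4f}\t{self.q3[i]:.4f}\t{self.coverage[i]}\n"
                )
        return path


def per_base_quality(reads: Iterable[ReadRecord]) -> PerBaseQuality:
    """Mean/median/quartiles of phred scores at every cycle.

    Quartiles use linear interpolation on the sorted per-cycle scores.
    """
    per_cycle: list[list[int]] = []
    length_distribution: dict[int, int] = {}
    for read in reads:
        scores = _scores(read.quality)
        length = len(scores)
        length_distribution[length] = length_distribution.get(length, 0) + 1
        while len(per_cycle) < length:
            per_cycle.append([])
        for i, s in enumerate(scores.tolist()):
            per_cycle[i].append(s)
    if not per_cycle:
        raise ValueError("empty input: no reads")
    mean, median, q1, q3, coverage = [], [], [], [], []
    for cycle_scores in per_cycle:
        arr = np.asarray(cycle_scores)
        mean.append(float(arr.mean()))
        median.append(float(np.median(arr)))
        q1.append(float(np.percentile(arr, 25)))
        q3.append(float(np.percentile(arr, 75)))
        coverage.append(len(cycle_scores))
    return PerBaseQuality(
        mean=mean,
        median=median,
        q1=q1,
        q3=q3,
        coverage=coverage,
        length_distribution=dict(sorted(length_distribution.items())),
    )


@dataclass
class RunSummary:
    """Headline per-sample metrics plus any red-flag threshold breaches."""

    read_count: int
    total_bases: int
    mean_q30_bases_per_read: float
    q30_read_pct: float
    mean_read_length: float
    gc_histogram: dict[int, int]
    flags: list[tuple[str, float, float]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"report_type": "readmetrics", **asdict(self)}, indent=2)

    def to_text(self) -> str:
        lines = [
            f"reads: {self.read_count}",
            f"total bases: {self.total_bases}",
            f"mean read length: {self.mean_read_length:.2f}",
            f"mean Q30+ bases per read: {self.mean_q30_bases_per_read:.2f}",
            f"reads with mean Q >= 30: {self.q30_read_pct:.2f}%",
        ]
        for name, value, threshold in self.flags:
            lines.append(f"RED FLAG: {name} = {value} below expected minimum {threshold}")
        return "\n".join(lines)


def q30_summary(
    reads: Iterable[ReadRecord], q_threshold: int = 30
) -> RunSummary:
    """Q30 yield metrics and per-read GC histogram over a read stream."""
    read_count = 0
    total_bases = 0
    q30_base_total = 0
    q30_reads = 0
    gc_hist: dict[int, int] = {}
    for read in reads:
        read_count += 1
        scores = _scores(read.quality)
        total_bases += len(scores)
        q30_base_total += int((scores >= q_threshold).sum())
        if len(scores) and float(scores.mean()) >= q_threshold:
            q30_reads += 1
        hist, _ = gc_read_histogram([read.sequence])
        for b, c in hist.items():
            gc_hist[b] = gc_hist.get(b, 0) + c
    if read_count == 0:
        raise ValueError("empty input: no reads")
    return RunSummary(
        read_count=read_count,
        total_bases=total_bases,
        mean_q30_bases_per_read=q30_base_total / read_count,
        q30_read_pct=100.0 * q30_reads / read_count,
        mean_read_length=total_bases / read_count,
        gc_histogram=dict(sorted(gc_hist.items())),
    )


def summarize_run(
    summary: RunSummary, thresholds: dict[str, float] | None = None
) -> RunSummary:
    """Attach red flags for every configured metric below its minimum.

    No thresholds are enabled by default; a flag (metric, value, threshold)
    is recorded iff value < threshold.
    """
    flags: list[tuple[str, float, float]] = []
    for name, threshold in (thresholds or {}).items():
        value = getattr(summary, name, None)
        if value is None:
            raise KeyError(f"unknown metric {name!r} in thresholds")
        if value < threshold:
            flags.append((name, float(value), float(threshold)))
    summary.flags = flags
    return summary
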