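"""K-mer contamination screening and filtering.

Reads are screened against reference k-mer tables pre-generated from whole
references (or single chromosomes of larger genomes).  Two headline
figures together indicate true contamination:

* the percentage of reads containing one or more reference k-mers, and
* the percentage of the reference's k-mers covered by the whole read file.

A high read-hit percentage with low reference coverage is the classic
shared-k-mer signature between related species (e.g. an E. coli screen of
another bacterium) rather than true contamination — `interpret_screen`
encodes exactly that logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Iterator

from knowyourdata.io_formats import ReadRecord, ReadPair, parse_fasta
from knowyourdata.kmer_core import (
    KmerTable,
    SubsampleSpec,
    count_kmers,
    sequence_kmer_values,
)

DEFAULT_SCREEN_K = 21


@dataclass
class ScreenReport:
    """Result bundle of one screen of a read set against one reference."""

    reference_name: str
    k: int
    reads_screened: int
    reads_with_hit: int
    reads_with_hit_pct: float
    ref_kmers_total: int
    ref_kmers_observed: int
    ref_covered_pct: float
    subsample_fraction: float

    def to_json(self) -> str:
        return json.dumps({"report_type": "screen", **asdict(self)}, indent=2)

    def to_tsv_row(self) -> str:
        return "\t".join(
            str(v)
            for v in (
                self.reference_name,
                self.k,
                self.reads_screened,
                self.reads_with_hit,
                f"{self.reads_with_hit_pct:.4f}",
                self.ref_kmers_total,
                self.ref_kmers_observed,
                f"{self.ref_covered_pct:.4f}",
                self.subsample_fraction,
            )
        )

    TSV_HEADER = (
        "reference\tk\treads_screened\treads_with_hit\treads_with_hit_pct"
        "\tref_kmers_total\tref_kmers_observed\tref_covered_pct\tsubsample_fraction"
    )


def build_reference_table(fasta_path: str, k: int = DEFAULT_SCREEN_K) -> KmerTable:
    """Canonical k-mer table over every sequence of a reference FASTA."""
    sequences = [seq for _, seq in parse_fasta(fasta_path)]
    if not sequences:
        raise ValueError(f"empty FASTA: {fasta_path}")
    return count_kmers(sequences, k)


def screen_reads(
    reads: Iterable[ReadRecord],
    ref_table: KmerTable,
    subsample: SubsampleSpec | None = None,
    reference_name: str = "reference",
) -> ScreenReport:
    """Screen a read stream against a reference table.

    Subsamples the stream (default: all reads if no spec given), counts
    reads carrying >= 1 reference k-mer, and tracks which distinct
    reference k-mers were observed anywhere in the sampled reads.
    """
    subsample = subsample or SubsampleSpec(fraction=1.0)
    ref_values = ref_table.value_set()
    k = ref_table.k
    reads_screened = 0
    reads_with_hit = 0
    observed: set[int] = set()
    for read in subsample.select(reads):
        reads_screened += 1
        hit = False
        for value in sequence_kmer_values(read.sequence, k).tolist():
            if value in ref_values:
                hit = True
                observed.add(value)
        if hit:
            reads_with_hit += 1
    if reads_screened == 0:
        raise ValueError("no reads sampled: cannot form screening percentages")
    total = len(ref_table)
    return ScreenReport(
        reference_name=reference_name,
        k=k,
        reads_screened=reads_screened,
        reads_with_hit=reads_with_hit,
        reads_with_hit_pct=100.0 * reads_with_hit / reads_screened,
        ref_kmers_total=total,
        ref_kmers_observed=len(observed),
        ref_covered_pct=100.0 * len(observed) / total if total else 0.0,
        subsample_fraction=subsample.fraction,
    )


def interpret_screen(
    report: ScreenReport,
    read_hit_threshold_pct: float = 5.0,
    coverage_threshold_pct: float = 20.0,
) -> str:
    """Classify a screen as true_contamination, shared_kmers_only or clean.

    True contamination needs both a substantial read-hit percentage and
    substantial reference coverage; read hits without coverage are shared
    k-mers between related organisms.
    """
    for threshold in (read_hit_threshold_pct, coverage_threshold_pct):
        if not (0.0 <= threshold <= 100.0):
            raise ValueError(f"threshold {threshold} outside [0, 100]")
    if report.reads_with_hit_pct >= read_hit_threshold_pct:
        if report.ref_covered_pct >= coverage_threshold_pct:
            return "true_contamination"
        return "shared_kmers_only"
    return "clean"


@dataclass
class FilterSummary:
    mode: str
    min_hit_kmers: int
    total: int
    kept: int
    removed: int


def _hit_kmer_count(sequence: str, ref_values: set[int], k: int) -> int:
    return sum(1 for v in sequence_kmer_values(sequence, k).tolist() if v in ref_values)


def filter_reads(
    items: Iterable[ReadRecord | ReadPair],
    ref_table: KmerTable,
    mode: str = "discard_hits",
    min_hit_kmers: int = 1,
) -> tuple[list, list, FilterSummary]:
    """Partition reads (or pairs) by reference k-mer hits; never subsampled.

    A read hits when it carries >= min_hit_kmers reference k-mers; a pair
    hits when either mate does (removing half a pair breaks pairing
    downstream).  discard_hits sends hits to `removed`; keep_hits sends
    them to `kept` — the two modes partition identically with labels
    swapped.
    """
    if mode not in ("discard_hits", "keep_hits"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if min_hit_kmers < 1:
        raise ValueError("min_hit_kmers must be >= 1")
    ref_values = ref_table.value_set()
    k = ref_table.k
    kept: list = []
    removed: list = []
    total = 0
    for item in items:
        total += 1
        if isinstance(item, ReadPair):
            hits = _hit_kmer_count(item.r1.sequence, ref_values, k) >= min_hit_kmers or (
                _hit_kmer_count(item.r2.sequence, ref_values, k) >= min_hit_kmers
            )
        else:
            hits = _hit_kmer_count(item.sequence, ref_values, k) >= min_hit_kmers
        is_removed = hits if mode == "discard_hits" else not hits
        (removed if is_removed else kept).append(item)
    summary = FilterSummary(
        mode=mode,
        min_hit_kmers=min_hit_kmers,
        total=total,
        kept=len(kept),
        removed=len(removed),
    )
    return kept, removed, summary


def write_screen_reports(
    reports: Iterable[ScreenReport], tsv_path: str, json_path: str
) -> None:
    reports = list(reports)
    with open(tsv_path, "wt") as handle:
        handle.write(ScreenReport.TSV_HEADER + "\n")
        for report in reports:
            handle.write(report.to_tsv_row() + "\n")
    with open(json_path, "wt") as handle:
        json.dump(
            [{"report_type": "screen", **asdict(r)} for r in reports], handle, indent=2
        )
        handle.write("\n")
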