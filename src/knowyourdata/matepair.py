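"""Nextera long-mate-pair (LMP) library analysis and junction clipping.

Nextera LMP preparation circularizes large fragments around a junction
adaptor; sequenced reads that cross the junction contain the 38-base
adaptor, and genomic sequence beyond it belongs to the distal fragment end
and must be clipped.  Pairs are categorized by where the adaptor was
found — A: both reads, B: read 2 only, C: read 1 only, D: neither — since
adaptor presence indicates a genuine mate pair rather than a library
artefact.  The module also estimates PCR duplication from read-prefix
signatures, profiles per-read GC, and, given alignments, classifies pair
orientation (mate pair / paired end / tandem) with insert-size histograms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

from knowyourdata.io_formats import AlignedPair, ReadPair, ReadRecord

# The Nextera junction adaptor: the 19-base transposon end sequence joined
# to its reverse complement.  The 38-mer is its own reverse complement, so
# detection is strand-neutral.
NEXTERA_JUNCTION = "CTGTCTCTTATACACATCTAGATGTGTATAAGAGACAG"

CATEGORIES = ("A", "B", "C", "D")


@dataclass
class AdaptorSpec:
    """Junction adaptor and matching tolerances.

    A window qualifies when mismatches <= max_mismatch_rate x overlap
    length (defaults allow 4 mismatches over the full 38-base window,
    scaled down for partial end overlaps of >= min_overlap bases).
    """

    junction_sequence: str = NEXTERA_JUNCTION
    min_overlap: int = 18
    max_mismatch_rate: float = 4 / 38

    def __post_init__(self) -> None:
        if self.min_overlap > len(self.junction_sequence):
            raise ValueError("min_overlap exceeds junction length")


def _mismatches(a: str, b: str, budget: int) -> int:
    count = 0
    for x, y in zip(a, b):
        if x != y:
            count += 1
            if count > budget:
                return count
    return count


def find_junction(read: ReadRecord | str, adaptor: AdaptorSpec | None = None) -> int | None:
    """Leftmost 0-based start of a junction match in the read, or None.

    Tests every full-junction window, plus end-overlapping prefixes of the
    junction at the read's 3' end and suffixes at the 5' end, down to
    min_overlap bases; the mismatch budget scales with overlap length.
    """
    adaptor = adaptor or AdaptorSpec()
    seq = read.sequence if isinstance(read, ReadRecord) else read
    junction = adaptor.junction_sequence
    jlen = len(junction)
    n = len(seq)
    best: int | None = None

    # 5' overhang: a suffix of the junction at the very start of the read.
    for overlap in range(min(jlen - 1, n), adaptor.min_overlap - 1, -1):
        budget = int(adaptor.max_mismatch_rate * overlap)
        if _mismatches(seq[:overlap], junction[jlen - overlap :], budget) <= budget:
            return 0

    full_budget = int(adaptor.max_mismatch_rate * jlen)
    for start in range(0, n - jlen + 1):
        if _mismatches(seq[start : start + jlen], junction, full_budget) <= full_budget:
            return start

    # 3' overhang: a prefix of the junction running off the read's end.
    for start in range(max(0, n - jlen + 1), n - adaptor.min_overlap + 1):
        overlap = n - start
        budget = int(adaptor.max_mismatch_rate * overlap)
        if _mismatches(seq[start:], junction[:overlap], budget) <= budget:
            return start
    return best


def classify_and_clip(
    pair: ReadPair, adaptor: AdaptorSpec | None = None, min_length: int = 25
) -> tuple[str, ReadPair | None]:
    """Categorize a pair by junction presence and clip at the junction.

    Each mate with a detected junction is truncated at the junction start.
    Pairs whose clipped mate falls below min_length are excluded from
    output (returned as None) but still counted under their category.
    """
    adaptor = adaptor or AdaptorSpec()
    pos1 = find_junction(pair.r1, adaptor)
    pos2 = find_junction(pair.r2, adaptor)
    if pos1 is not None and pos2 is not None:
        category = "A"
    elif pos2 is not None:
        category = "B"
    elif pos1 is not None:
        category = "C"
    else:
        category = "D"
    r1 = pair.r1 if pos1 is None else pair.r1.trimmed(0, pos1)
    r2 = pair.r2 if pos2 is None else pair.r2.trimmed(0, pos2)
    if len(r1) < min_length or len(r2) < min_length:
        return category, None
    return category, ReadPair(r1, r2)


@dataclass
class MatePairReport:
    """Per-library LMP analysis summary."""

    category_counts: dict[str, int]
    excluded_too_short: dict[str, int]
    duplication_rate_pct: float
    gc_histogram: dict[int, int]
    total_pairs: int
    output_paths: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"report_type": "matepair", **asdict(self)}, indent=2)


def duplicate_rate(
    pairs: Iterable[ReadPair], signature_bases: int = 16
) -> tuple[float, int, int]:
    """PCR duplication estimate from raw read-prefix signatures.

    Signature = first signature_bases of R1 + first signature_bases of R2,
    taken from the unclipped reads (clipping varies with adaptor position;
    prefixes are stable).  Returns (rate_pct, pairs_considered, skipped):
    rate = 100 x (1 - distinct signatures / pairs considered).
    """
    signatures: set[str] = set()
    considered = 0
    skipped = 0
    for pair in pairs:
        if len(pair.r1) < signature_bases or len(pair.r2) < signature_bases:
            skipped += 1
            continue
        considered += 1
        signatures.add(pair.r1.sequence[:signature_bases] + pair.r2.sequence[:signature_bases])
    if considered == 0:
        raise ValueError("no pairs long enough for duplicate signatures")
    return 100.0 * (1.0 - len(signatures) / considered), considered, skipped


def gc_read_histogram(
    reads: Iterable[ReadRecord | str], bin_width_pct: float = 1.0
) -> tuple[dict[int, int], int]:
    """Histogram of per-read GC percentage.

    GC% = 100 x (G+C) / (A+C+G+T): N bases are excluded from the
    denominator.  All-N reads are skipped and counted.  Bins are indexed
    by floor(gc / bin_width); returns (histogram, skipped_count).
    """
    hist: dict[int, int] = {}
    skipped = 0
    for read in reads:
        seq = read.sequence if isinstance(read, ReadRecord) else read
        called = sum(seq.count(b) for b in "ACGT")
        if called == 0:
            skipped += 1
            continue
        gc = 100.0 * (seq.count("G") + seq.count("C")) / called
        bin_index = min(int(gc / bin_width_pct), int(100 / bin_width_pct))
        hist[bin_index] = hist.get(bin_index, 0) + 1
    return dict(sorted(hist.items())), skipped


ORIENTATIONS = ("mate_pair", "paired_end", "tandem")


@dataclass
class OrientationReport:
    """Insert-size histograms per orientation (and per category if given)."""

    insert_histograms: dict[str, dict[int, int]]
    discordant: int
    total: int

    def to_json(self) -> str:
        return json.dumps({"report_type": "orientation", **asdict(self)}, indent=2)


def classify_orientation(pair: AlignedPair) -> tuple[str, int] | None:
    """Orientation label and insert size, or None when discordant.

    With `left` the mate at the smaller leftmost position: inward
    (left +, right -) is paired-end geometry, outward (left -, right +) is
    mate-pair geometry, equal strands are tandem.  Insert size is the
    1-based inclusive span between the outermost aligned coordinates.
    """
    if not pair.same_reference:
        return None
    if pair.pos1 <= pair.pos2:
        left_pos, left_strand, left_alen = pair.pos1, pair.strand1, pair.alen1
        right_pos, right_strand, right_alen = pair.pos2, pair.strand2, pair.alen2
    else:
        left_pos, left_strand, left_alen = pair.pos2, pair.strand2, pair.alen2
        right_pos, right_strand, right_alen = pair.pos1, pair.strand1, pair.alen1
    if left_strand == right_strand:
        orientation = "tandem"
    elif left_strand == "+":
        orientation = "paired_end"
    else:
        orientation = "mate_pair"
    outer_end = max(left_pos + left_alen - 1, right_pos + right_alen - 1)
    insert = outer_end - left_pos + 1
    return orientation, insert


def orientation_analysis(
    aligned_pairs: Iterable[AlignedPair],
    categories: dict[str, str] | None = None,
) -> OrientationReport:
    """Classify every aligned pair; bucket insert sizes per orientation.

    When a {read name -> category} mapping is supplied, histograms are
    keyed "category/orientation"; otherwise by orientation alone.
    Unmapped mates and cross-reference pairs land in the discordant count.
    """
    histograms: dict[str, dict[int, int]] = {}
    discordant = 0
    total = 0
    for pair in aligned_pairs:
        total += 1
        result = classify_orientation(pair)
        if result is None:
            discordant += 1
            continue
        orientation, insert = result
        key = orientation
        if categories is not None:
            key = f"{categories.get(pair.name, '?')}/{orientation}"
        hist = histograms.setdefault(key, {})
        hist[insert] = hist.get(insert, 0) + 1
    return OrientationReport(insert_histograms=histograms, discordant=discordant, total=total)


def analyze_library(
    pairs: Iterable[ReadPair],
    adaptor: AdaptorSpec | None = None,
    min_length: int = 25,
    signature_bases: int = 16,
    output_prefix: str | None = None,
    write_category_d: bool = False,
) -> MatePairReport:
    """Full LMP pass: classify, clip, profile GC and duplication.

    With output_prefix set, clipped pairs are written per category as
    interleaved FASTQ "<prefix>_<category>.fastq" (category D optional,
    since D pairs are probable artefacts).
    """
    from knowyourdata.io_formats import write_fastq

    adaptor = adaptor or AdaptorSpec()
    category_counts = {c: 0 for c in CATEGORIES}
    excluded = {c: 0 for c in CATEGORIES}
    clipped_out: dict[str, list[ReadRecord]] = {c: [] for c in CATEGORIES}
    gc_hist: dict[int, int] = {}
    signatures: set[str] = set()
    sig_considered = 0
    total = 0
    for pair in pairs:
        total += 1
        if len(pair.r1) >= signature_bases and len(pair.r2) >= signature_bases:
            sig_considered += 1
            signatures.add(
                pair.r1.sequence[:signature_bases] + pair.r2.sequence[:signature_bases]
            )
        for read in (pair.r1, pair.r2):
            called = sum(read.sequence.count(b) for b in "ACGT")
            if called:
                gc_bin = min(int(100.0 * (read.sequence.count("G") + read.sequence.count("C")) / called), 100)
                gc_hist[gc_bin] = gc_hist.get(gc_bin, 0) + 1
        category, clipped = classify_and_clip(pair, adaptor, min_length)
        category_counts[category] += 1
        if clipped is None:
            excluded[category] += 1
        else:
            clipped_out[category].extend((clipped.r1, clipped.r2))
    dup_rate = (
        100.0 * (1.0 - len(signatures) / sig_considered) if sig_considered else 0.0
    )
    output_paths: dict[str, str] = {}
    if output_prefix is not None:
        wanted = CATEGORIES if write_category_d else ("A", "B", "C")
        for category in wanted:
            path = f"{output_prefix}_{category}.fastq"
            write_fastq(clipped_out[category], path)
            output_paths[category] = path
    return MatePairReport(
        category_counts=category_counts,
        excluded_too_short=excluded,
        duplication_rate_pct=dup_rate,
        gc_histogram=dict(sorted(gc_hist.items())),
        total_pairs=total,
        output_paths=output_paths,
    )
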