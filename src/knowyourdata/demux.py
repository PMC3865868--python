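"""Demultiplexing of reads carrying variable-offset inline barcodes.

RAD-Seq reads begin at a restriction site: read 1 carries an inline sample
barcode that connects directly to genomic sequence through the enzyme's
overhang remnant.  To stop the overhang occupying the same cycles in
every read (which degrades basecalling), the protocol offsets the barcode
by 0-n filler bases; the demultiplexer therefore scores every
(sample, offset) candidate jointly — barcode mismatches at the offset
window, with the overhang required immediately after — and routes each
read to the unique best candidate, to "ambiguous" on a tie, or to
"undetermined" when nothing qualifies.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator

from knowyourdata.io_formats import ReadPair, ReadRecord, write_fastq


@dataclass
class BarcodeSpec:
    """One sample's inline barcode, its allowed offsets, and the overhang."""

    sample_name: str
    barcode: str
    allowed_offsets: frozenset[int]
    overhang: str

    def __post_init__(self) -> None:
        if not (4 <= len(self.barcode) <= 10):
            raise ValueError(
                f"barcode length {len(self.barcode)} outside 4-10 for {self.sample_name}"
            )
        if any(o < 0 for o in self.allowed_offsets):
            raise ValueError("offsets must be non-negative")


def read_sample_sheet(path: str | os.PathLike) -> list[BarcodeSpec]:
    """Load a TSV sample sheet: sample, barcode, offsets (comma-sep), overhang."""
    specs: list[BarcodeSpec] = []
    with open(os.fspath(path), "rt") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("sample\t"):
                continue
            sample, barcode, offsets, overhang = line.split("\t")
            specs.append(
                BarcodeSpec(
                    sample_name=sample,
                    barcode=barcode.upper(),
                    allowed_offsets=frozenset(int(o) for o in offsets.split(",")),
                    overhang=overhang.upper(),
                )
            )
    _validate_specs(specs)
    return specs


def _validate_specs(specs: list[BarcodeSpec]) -> None:
    names = [s.sample_name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample names in sheet")
    barcodes = [s.barcode for s in specs]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in sheet")
    overhangs = {s.overhang for s in specs}
    if len(overhangs) > 1:
        raise ValueError("overhang must be identical across all samples in a run")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class BarcodeMatch:
    sample: str
    offset: int
    mismatches: int


def match_barcode(
    read: ReadRecord | str,
    specs: Iterable[BarcodeSpec],
    max_barcode_mismatch: int = 1,
    max_overhang_mismatch: int = 0,
) -> BarcodeMatch | str:
    """Best (sample, offset) for a read, or "undetermined" / "ambiguous".

    All (spec, offset) candidates are scored jointly (no first-match
    shortcut): a candidate needs barcode mismatches <= max_barcode_mismatch
    at [offset, offset+len) and the overhang immediately after with
    <= max_overhang_mismatch mismatches (exact by default — the overhang is
    what disambiguates the offset).  The unique minimum-mismatch candidate
    wins; a tie at the minimum is ambiguous.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    candidates: list[BarcodeMatch] = []
    for spec in specs:
        blen = len(spec.barcode)
        olen = len(spec.overhang)
        for offset in sorted(spec.allowed_offsets):
            end = offset + blen + olen
            if end > len(seq):
                continue
            bc_mm = _hamming(seq[offset : offset + blen], spec.barcode)
            if bc_mm > max_barcode_mismatch:
                continue
            oh_mm = _hamming(seq[offset + blen : end], spec.overhang)
            if oh_mm > max_overhang_mismatch:
                continue
            candidates.append(BarcodeMatch(spec.sample_name, offset, bc_mm))
    if not candidates:
        return "undetermined"
    best = min(c.mismatches for c in candidates)
    winners = [c for c in candidates if c.mismatches == best]
    if len(winners) > 1:
        return "ambiguous"
    return winners[0]


@dataclass
class DemuxReport:
    """Routing summary; assigned + undetermined + ambiguous == input count."""

    assigned: dict[str, int]
    undetermined: int
    ambiguous: int
    total: int
    output_paths: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"report_type": "demux", **asdict(self)}, indent=2)


def demultiplex(
    items: Iterable[ReadRecord | ReadPair],
    specs: list[BarcodeSpec],
    output_dir: str | os.PathLike | None = None,
    trim: bool = True,
    max_barcode_mismatch: int = 1,
    max_overhang_mismatch: int = 0,
    gzip_output: bool = False,
) -> DemuxReport:
    """Route reads (or pairs) to per-sample FASTQ files.

    Matching always looks at R1.  With trim=True the offset filler and
    barcode are removed from R1; the overhang is retained because it is
    genomic sequence.  R2 is never modified.  Unassigned reads go to
    "Undetermined" (ambiguous ones to "Ambiguous") so the output files
    partition the input exactly.
    """
    _validate_specs(specs)
    buckets: dict[str, list] = {s.sample_name: [] for s in specs}
    buckets["Undetermined"] = []
    buckets["Ambiguous"] = []
    assigned = {s.sample_name: 0 for s in specs}
    barcode_len = {s.sample_name: len(s.barcode) for s in specs}
    undetermined = 0
    ambiguous = 0
    total = 0
    for item in items:
        total += 1
        r1 = item.r1 if isinstance(item, ReadPair) else item
        match = match_barcode(r1, specs, max_barcode_mismatch, max_overhang_mismatch)
        if match == "undetermined":
            undetermined += 1
            buckets["Undetermined"].append(item)
            continue
        if match == "ambiguous":
            ambiguous += 1
            buckets["Ambiguous"].append(item)
            continue
        assert isinstance(match, BarcodeMatch)
        assigned[match.sample] += 1
        if trim:
            start = match.offset + barcode_len[match.sample]
            trimmed_r1 = r1.trimmed(start)
            item = (
                ReadPair(trimmed_r1, item.r2)
                if isinstance(item, ReadPair)
                else trimmed_r1
            )
        buckets[match.sample].append(item)
    output_paths: dict[str, str] = {}
    if output_dir is not None:
        output_dir = os.fspath(output_dir)
        os.makedirs(output_dir, exist_ok=True)
        for name, bucket in buckets.items():
            output_paths.update(
                _write_bucket(name, bucket, output_dir, gzip_output)
            )
    return DemuxReport(
        assigned=assigned,
        undetermined=undetermined,
        ambiguous=ambiguous,
        total=total,
        output_paths=output_paths,
    )


def _write_bucket(
    name: str, bucket: list, output_dir: str, gzip_output: bool
) -> dict[str, str]:
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    paths: dict[str, str] = {}
    paired = bool(bucket) and isinstance(bucket[0], ReadPair)
    r1_path = os.path.join(output_dir, f"{name}_R1{suffix}")
    if paired:
        paths[f"{name}_R1"] = write_fastq((p.r1 for p in bucket), r1_path, gzip_output)
        r2_path = os.path.join(output_dir, f"{name}_R2{suffix}")
        paths[f"{name}_R2"] = write_fastq((p.r2 for p in bucket), r2_path, gzip_output)
    else:
        paths[f"{name}_R1"] = write_fastq(iter(bucket), r1_path, gzip_output)
    return paths
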