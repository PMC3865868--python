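"""Readers and writers for the standard formats the toolkit touches.

FASTQ (4-line, phred+33, optionally gzipped), FASTA, a minimal SAM pair
reader built on pysam, and md5sum-compatible checksum manifests.
Qualities are fixed at phred+33 (Sanger); every platform the toolkit
targets emits that encoding, and phred+64 input is rejected rather than
guessed at.
"""

from __future__ import annotations

import gzip
import hashlib
import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

import pysam

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqParseError(ValueError):
    """Raised for a malformed FASTQ record; carries the 1-based record index."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: identifier, bases and phred+33 quality string."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"quality length {len(self.quality)} != sequence length "
                f"{len(self.sequence)} for read {self.read_id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def trimmed(self, start: int = 0, end: int | None = None) -> "ReadRecord":
        """Sub-read over [start, end); quality trimmed in step."""
        return ReadRecord(self.read_id, self.sequence[start:end], self.quality[start:end])


@dataclass(frozen=True)
class ReadPair:
    """An R1/R2 read pair sharing a read-id stem."""

    r1: ReadRecord
    r2: ReadRecord

    @property
    def stem(self) -> str:
        return id_stem(self.r1.read_id)


@dataclass(frozen=True)
class AlignedPair:
    """Both primary alignments of a read pair, reduced to what orientation
    analysis needs: reference, leftmost positions (1-based), strands and
    reference-aligned lengths."""

    name: str
    ref_name1: str | None
    ref_name2: str | None
    pos1: int
    pos2: int
    strand1: str
    strand2: str
    alen1: int
    alen2: int
    mapped1: bool
    mapped2: bool

    @property
    def same_reference(self) -> bool:
        return (
            self.mapped1
            and self.mapped2
            and self.ref_name1 is not None
            and self.ref_name1 == self.ref_name2
        )


def id_stem(read_id: str) -> str:
    """Read-id stem with a trailing '/1' or '/2' mate suffix removed."""
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    return read_id


def _open_text(path: str | os.PathLike, mode: str = "rt") -> IO[str]:
    path = os.fspath(path)
    if "r" in mode:
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fastq(path: str | os.PathLike) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a plain or gzipped 4-line FASTQ file.

    Raises FastqParseError naming the offending record for truncated
    records, missing '@'/'+' markers, or sequence/quality length mismatch.
    Qualities outside printable phred+33 range (ASCII 33-126) are rejected,
    which also catches phred+64 files whose scores exceed Q62.
    """
    with _open_text(path) as handle:
        index = 0
        while True:
            header = handle.readline()
            if not header:
                return
            index += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(f"header does not start with '@': {header!r}", index)
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            qual = handle.readline()
            if not plus or not qual:
                raise FastqParseError("truncated record", index)
            if not plus.startswith("+"):
                raise FastqParseError(f"separator line does not start with '+'", index)
            qual = qual.rstrip("\n")
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"quality length {len(qual)} != sequence length {len(seq)}", index
                )
            if any(not (33 <= ord(c) <= 126) for c in qual):
                raise FastqParseError("quality characters outside ASCII 33-126", index)
            yield ReadRecord(header[1:], seq.upper(), qual)


def write_fastq(
    records: Iterable[ReadRecord], path: str | os.PathLike, gzip_output: bool = False
) -> str:
    """Write records as 4-line FASTQ; round-trips byte-identically."""
    path = os.fspath(path)
    if gzip_output and not path.endswith(".gz"):
        path += ".gz"
    opener = gzip.open if gzip_output else open
    with opener(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
    return path


def parse_fastq_pairs(
    r1_path: str | os.PathLike, r2_path: str | os.PathLike
) -> Iterator[ReadPair]:
    """Zip two FASTQ files positionally into ReadPairs, checking id stems."""
    for r1, r2 in zip(parse_fastq(r1_path), parse_fastq(r2_path), strict=True):
        if id_stem(r1.read_id) != id_stem(r2.read_id):
            raise ValueError(
                f"paired files out of sync: {r1.read_id!r} vs {r2.read_id!r}"
            )
        yield ReadPair(r1, r2)


def parse_fasta(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Stream (id, sequence) tuples; id is the header token before whitespace."""
    current_id: str | None = None
    chunks: list[str] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if current_id is not None:
                    yield current_id, "".join(chunks)
                current_id = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            else:
                if current_id is None:
                    raise ValueError("FASTA sequence data before any '>' header")
                chunks.append(line.upper())
    if current_id is not None:
        yield current_id, "".join(chunks)


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | os.PathLike, width: int = 80
) -> str:
    path = os.fspath(path)
    with open(path, "wt") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    return path


def parse_sam_pairs(path: str | os.PathLike) -> Iterator[AlignedPair]:
    """Assemble AlignedPairs from a SAM file's primary alignments.

    Secondary (0x100) and supplementary (0x800) records are skipped.  A pair
    is emitted once both primary mates of a QNAME have been seen; aligned
    length is the reference-consuming CIGAR span.  Unmapped mates carry
    mapped=False and a position of 0.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_secondary or seg.is_supplementary:
                continue
            name = seg.query_name
            mate = pending.pop(name, None)
            if mate is None:
                pending[name] = seg
                continue
            first, second = (mate, seg) if mate.is_read1 or seg.is_read2 else (seg, mate)
            yield _make_aligned_pair(name, first, second)


def _segment_fields(seg: pysam.AlignedSegment) -> tuple[str | None, int, str, int, bool]:
    if seg.is_unmapped:
        return None, 0, "+", 0, False
    return (
        seg.reference_name,
        seg.reference_start + 1,
        "-" if seg.is_reverse else "+",
        seg.reference_length or 0,
        True,
    )


def _make_aligned_pair(
    name: str, first: pysam.AlignedSegment, second: pysam.AlignedSegment
) -> AlignedPair:
    ref1, pos1, strand1, alen1, mapped1 = _segment_fields(first)
    ref2, pos2, strand2, alen2, mapped2 = _segment_fields(second)
    return AlignedPair(
        name=name,
        ref_name1=ref1,
        ref_name2=ref2,
        pos1=pos1,
        pos2=pos2,
        strand1=strand1,
        strand2=strand2,
        alen1=alen1,
        alen2=alen2,
        mapped1=mapped1,
        mapped2=mapped2,
    )


def md5_manifest(
    paths: Iterable[str | os.PathLike], manifest_path: str | os.PathLike | None = None
) -> list[tuple[str, str]]:
    """MD5-checksum files, optionally writing an md5sum-compatible manifest.

    Manifest lines are "<md5><two spaces><path>", matching the format the
    standard md5sum utility consumes for verification.
    """
    entries: list[tuple[str, str]] = []
    for path in paths:
        path = os.fspath(path)
        digest = hashlib.md5()
        with open(path, "rb") as handle:
            for block in iter(lambda: handle.read(1 << 20), b""):
                digest.update(block)
        entries.append((path, digest.hexdigest()))
    if manifest_path is not None:
        with open(os.fspath(manifest_path), "wt") as handle:
            for path, hexdigest in entries:
                handle.write(f"{hexdigest}  {path}\n")
    return entries
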