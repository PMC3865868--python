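"""Canonical k-mer extraction, counting with subsampling, and spectrum
histograms — the shared engine behind contamination screening and spectra.

K-mers are formed by sliding a window of k bases one base at a time over a
read; each window overlaps the next in all but one base.  Counting is
strand-neutral: every window is folded onto its canonical form, the
lexicographic minimum (A<C<G<T) of the k-mer and its reverse complement.
Windows containing N are skipped entirely.

Internally k-mers are packed 2 bits per base into uint64 (so k <= 31),
which makes the integer order identical to lexicographic order and lets
numpy do the heavy lifting; the public surface speaks strings.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from knowyourdata.io_formats import ReadRecord, reverse_complement

MAX_K = 31

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = "ACGT"


@dataclass
class SubsampleSpec:
    """How to subsample a read stream before counting.

    The default fraction of 0.10 mirrors routine screening practice (one
    read in ten is plenty to detect contamination and is 10x faster).
    Systematic mode takes every round(1/fraction)-th read and is exactly
    reproducible; random mode Bernoulli-samples under a fixed seed.
    """

    fraction: float = 0.10
    mode: str = "systematic"  # systematic | random
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"subsample fraction must be in (0,1], got {self.fraction}")
        if self.mode not in ("systematic", "random"):
            raise ValueError(f"unknown subsample mode {self.mode!r}")

    def select(self, reads: Iterable[ReadRecord]) -> Iterator[ReadRecord]:
        if self.fraction == 1.0:
            yield from reads
            return
        if self.mode == "systematic":
            step = round(1.0 / self.fraction)
            for i, read in enumerate(reads):
                if i % step == 0:
                    yield read
        else:
            rng = np.random.default_rng(self.seed)
            for read in reads:
                if rng.random() < self.fraction:
                    yield read


@dataclass
class KmerTable:
    """Canonical-kmer -> count mapping at fixed k.

    Doubles as a presence set when screening reads against a reference.
    """

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.k <= MAX_K):
            raise ValueError(f"k must be in [1, {MAX_K}], got {self.k}")

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.counts

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, KmerTable)
            and self.k == other.k
            and self.counts == other.counts
        )

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def value_set(self) -> set[int]:
        """The table's k-mers as packed uint64 codes (for fast membership)."""
        return {encode_kmer(kmer) for kmer in self.counts}


def encode_kmer(kmer: str) -> int:
    """Pack a k-mer into an integer, 2 bits per base, A=0 C=1 G=2 T=3."""
    value = 0
    for base in kmer:
        code = _CODE[ord(base)]
        if code > 3:
            raise ValueError(f"non-ACGT base in kmer {kmer!r}")
        value = (value << 2) | int(code)
    return value


def decode_kmer(value: int, k: int) -> str:
    out = []
    for shift in range((k - 1) * 2, -1, -2):
        out.append(_BASES[(value >> shift) & 3])
    return "".join(out)


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Idempotent; rejects non-ACGT characters.
    """
    rc = reverse_complement(kmer)
    if "N" in kmer or any(c not in "ACGT" for c in kmer):
        raise ValueError(f"non-ACGT base in kmer {kmer!r}")
    return min(kmer, rc)


def _sequence_kmer_values(seq: str, k: int) -> np.ndarray:
    """Canonical packed values for every N-free window of one sequence."""
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    invalid = (codes > 3).astype(np.int64)
    m = n - k + 1
    bad = np.cumsum(invalid)
    window_ok = (bad[k - 1 :] - np.concatenate(([0], bad[:-k]))) == 0
    if not window_ok.any():
        return np.empty(0, dtype=np.uint64)
    # Pack each window with k shifted adds; avoids an m-by-k temporary.
    # N positions carry code 4, polluting only windows already masked out.
    codes64 = (codes & np.uint8(3)).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    rc_codes64 = np.uint64(3) - codes64
    for j in range(k):
        fwd |= codes64[j : j + m] << np.uint64(2 * (k - 1 - j))
        rev |= rc_codes64[j : j + m] << np.uint64(2 * j)
    return np.minimum(fwd, rev)[window_ok]


def sequence_kmer_values(seq: str, k: int) -> np.ndarray:
    """Public alias: canonical packed k-mer values of one sequence, in order."""
    return _sequence_kmer_values(seq, k)


def count_kmers(
    reads: Iterable[ReadRecord | str],
    k: int,
    subsample: SubsampleSpec | None = None,
) -> KmerTable:
    """Count canonical k-mers over a (possibly subsampled) read stream.

    A read of length L contributes max(0, L-k+1) windows minus any window
    containing an N.  Reads shorter than k contribute nothing.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K}, got {k}")
    seqs = (r.sequence if isinstance(r, ReadRecord) else r for r in reads)
    if subsample is not None:
        # SubsampleSpec.select is typed for ReadRecord but only enumerates.
        seqs = subsample.select(seqs)  # type: ignore[arg-type]
    counts: dict[int, int] = {}
    chunk: list[str] = []
    chunk_len = 0
    # Joining reads on 'N' keeps the vectorized path hot: the separator
    # windows are discarded by the N rule, so per-read and joined counting
    # are identical.
    for seq in seqs:
        chunk.append(seq)
        chunk_len += len(seq)
        if chunk_len >= 1 << 20:
            _accumulate(counts, "N".join(chunk), k)
            chunk, chunk_len = [], 0
    if chunk:
        _accumulate(counts, "N".join(chunk), k)
    return KmerTable(k=k, counts={decode_kmer(v, k): c for v, c in counts.items()})


def _accumulate(counts: dict[int, int], seq: str, k: int) -> None:
    values = _sequence_kmer_values(seq, k)
    if values.size == 0:
        return
    uniq, cnt = np.unique(values, return_counts=True)
    for v, c in zip(uniq.tolist(), cnt.tolist()):
        counts[v] = counts.get(v, 0) + c


def spectrum(table: KmerTable) -> dict[int, int]:
    """K-mer spectrum: multiplicity m -> number of distinct k-mers seen m times.

    The conservation invariant holds by construction: the histogram's values
    sum to the number of distinct k-mers in the table.
    """
    bins: dict[int, int] = {}
    for count in table.counts.values():
        bins[count] = bins.get(count, 0) + 1
    return dict(sorted(bins.items()))


_TABLE_MAGIC = "#knowyourdata kmer-table v1"


def save_table(table: KmerTable, path: str | os.PathLike) -> str:
    """Serialize a table as sorted TSV with a self-describing header."""
    path = os.fspath(path)
    with open(path, "wt") as handle:
        handle.write(f"{_TABLE_MAGIC} k={table.k}\n")
        for kmer in sorted(table.counts):
            handle.write(f"{kmer}\t{table.counts[kmer]}\n")
    return path


def load_table(path: str | os.PathLike, expect_k: int | None = None) -> KmerTable:
    """Load a table saved by save_table; load(save(T)) == T exactly."""
    with open(os.fspath(path), "rt") as handle:
        header = handle.readline().rstrip("\n")
        if not header.startswith(_TABLE_MAGIC):
            raise ValueError(f"not a knowyourdata kmer-table file: {path}")
        try:
            k = int(header.rsplit("k=", 1)[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"malformed kmer-table header: {header!r}") from exc
        if expect_k is not None and k != expect_k:
            raise ValueError(f"table has k={k}, expected k={expect_k}")
        counts: dict[str, int] = {}
        for line in handle:
            kmer, _, count = line.rstrip("\n").partition("\t")
            if len(kmer) != k:
                raise ValueError(f"kmer {kmer!r} does not match table k={k}")
            counts[kmer] = int(count)
    return KmerTable(k=k, counts=counts)
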