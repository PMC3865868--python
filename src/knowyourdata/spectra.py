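"""K-mer spectrum analysis: per-file spectra and their interpretation.

A k-mer spectrum plots coverage against the count of k-mers with that
coverage.  Spectra are computed separately for read 1, read 2 and their
pooled sum.  The initial peak around multiplicity 1 is dominated by
sequencing errors (each substitution typically creates up to k novel
k-mers); the shorter, wider peak(s) beyond it carry the signal.  A single
main peak centred near the sequencing depth indicates a homozygous sample;
a secondary peak near half the main multiplicity indicates heterozygosity
(heterozygous sites contribute k-mers from only one haplotype, so at half
depth).  The total k-mer mass above the error threshold divided by the
main-peak multiplicity estimates the genome's distinct k-mer content — a
standard proxy for genome size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from knowyourdata.io_formats import ReadRecord
from knowyourdata.kmer_core import KmerTable, count_kmers, spectrum

DEFAULT_SPECTRA_K = 31


@dataclass
class SpectraSet:
    """Spectra for R1, R2 and the pooled (combined) counts at fixed k.

    `combined` is the spectrum of the pooled k-mer counts, not the sum of
    the two histograms: a k-mer seen m1 times in R1 and m2 in R2 lands in
    bin m1+m2.
    """

    k: int
    r1: dict[int, int]
    r2: dict[int, int] = field(default_factory=dict)
    combined: dict[int, int] = field(default_factory=dict)


@dataclass
class SpectraAnalysis:
    """Interpretation of one spectrum."""

    error_threshold: int
    peaks: list[tuple[int, float]]
    main_peak: int | None
    zygosity: str  # homozygous | heterozygous | undetermined
    genome_size_estimate: float

    def to_json(self) -> str:
        return json.dumps({"report_type": "spectra", **asdict(self)}, indent=2)


def compute_spectra(
    r1_reads: Iterable[ReadRecord],
    r2_reads: Iterable[ReadRecord] | None = None,
    k: int = DEFAULT_SPECTRA_K,
) -> SpectraSet:
    """Count R1 and R2 separately, pool the counts, and histogram all three."""
    t1 = count_kmers(r1_reads, k)
    if r2_reads is None:
        return SpectraSet(k=k, r1=spectrum(t1), r2={}, combined=spectrum(t1))
    t2 = count_kmers(r2_reads, k)
    pooled_counts = dict(t1.counts)
    for kmer, count in t2.counts.items():
        pooled_counts[kmer] = pooled_counts.get(kmer, 0) + count
    pooled = KmerTable(k=k, counts=pooled_counts)
    return SpectraSet(k=k, r1=spectrum(t1), r2=spectrum(t2), combined=spectrum(pooled))


def _dense(hist: dict[int, int], max_m: int | None = None) -> np.ndarray:
    """Histogram as a dense array indexed by multiplicity (index 0 unused)."""
    if not hist:
        return np.zeros(1)
    top = max_m or max(hist)
    dense = np.zeros(top + 1)
    for m, count in hist.items():
        if m <= top:
            dense[m] = count
    return dense


def find_error_threshold(hist: dict[int, int]) -> tuple[int, bool]:
    """First local minimum separating the error peak from the signal.

    Returns (threshold, determined): the smallest multiplicity m with
    bins[m+1] > bins[m].  K-mers at multiplicity <= threshold are treated
    as error k-mers.  A monotone-decreasing histogram has no valley; the
    threshold falls back to 1 and `determined` is False.
    """
    if not hist:
        raise ValueError("empty histogram")
    dense = _dense(hist)
    for m in range(1, len(dense) - 1):
        if dense[m + 1] > dense[m]:
            return m, True
    return 1, False


def _smooth(dense: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return dense.astype(float)
    kernel = np.ones(window) / window
    # 'same' keeps bin alignment; edges see a shrunken effective window.
    return np.convolve(dense, kernel, mode="same")


def analyze_spectrum(
    hist: dict[int, int],
    smoothing_window: int = 5,
    het_tolerance: float = 0.25,
) -> SpectraAnalysis:
    """Find peaks above the error threshold and interpret them.

    Peaks are local maxima of the moving-average-smoothed histogram
    restricted to multiplicities above the error threshold.  Zygosity is
    heterozygous when a secondary peak sits within +/- het_tolerance of
    half the main peak's multiplicity.  Genome size (in distinct k-mers)
    = total above-threshold k-mer mass / main-peak multiplicity.
    """
    threshold, determined = find_error_threshold(hist)
    dense = _dense(hist)
    smoothed = _smooth(dense, smoothing_window)
    peaks: list[tuple[int, float]] = []
    for m in range(threshold + 1, len(dense)):
        left = smoothed[m - 1] if m - 1 >= 0 else 0.0
        right = smoothed[m + 1] if m + 1 < len(smoothed) else 0.0
        if smoothed[m] > 0 and smoothed[m] >= left and smoothed[m] > right:
            # Flat-top ties resolve to the leftmost bin of the plateau.
            if peaks and m - peaks[-1][0] == 1 and smoothed[m] == peaks[-1][1]:
                continue
            peaks.append((m, float(smoothed[m])))
    if not peaks:
        return SpectraAnalysis(
            error_threshold=threshold,
            peaks=peaks,
            main_peak=None,
            zygosity="undetermined",
            genome_size_estimate=0.0,
        )
    main_peak = max(peaks, key=lambda p: p[1])[0]
    mass = sum(m * c for m, c in hist.items() if m > threshold)
    genome_size = mass / main_peak
    # A heterozygous sample shows two peaks an octave apart: haplotype-
    # specific k-mers at half the depth of shared ones.  Either peak can
    # be the taller depending on the SNP rate, so both directions count.
    # Noise bumps in the tail must not count: a companion peak needs real
    # support (>= 10% of the main peak's height).
    zygosity = "homozygous"
    main_height = max(height for m, height in peaks if m == main_peak)
    half = main_peak / 2.0
    double = main_peak * 2.0
    for m, height in peaks:
        if m == main_peak or height < 0.1 * main_height:
            continue
        if abs(m - half) <= het_tolerance * half or abs(m - double) <= het_tolerance * double:
            zygosity = "heterozygous"
            break
    return SpectraAnalysis(
        error_threshold=threshold,
        peaks=peaks,
        main_peak=main_peak,
        zygosity=zygosity,
        genome_size_estimate=genome_size,
    )


def export_overlay(
    spectra_set: SpectraSet,
    path: str,
    analysis: SpectraAnalysis | None = None,
    plot_path: str | None = None,
) -> str:
    """Write the R1/R2/combined overlay as dense TSV; optionally plot it.

    Multiplicities with zero counts inside the covered range are emitted
    as explicit zeros so the file plots directly.
    """
    top = max(
        [max(h) for h in (spectra_set.r1, spectra_set.r2, spectra_set.combined) if h],
        default=0,
    )
    with open(path, "wt") as handle:
        handle.write("multiplicity\tr1\tr2\tcombined\n")
        for m in range(1, top + 1):
            handle.write(
                f"{m}\t{spectra_set.r1.get(m, 0)}\t{spectra_set.r2.get(m, 0)}"
                f"\t{spectra_set.combined.get(m, 0)}\n"
            )
    if plot_path is not None:
        _plot_overlay(spectra_set, analysis, plot_path)
    return path


def _plot_overlay(
    spectra_set: SpectraSet, analysis: SpectraAnalysis | None, plot_path: str
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, hist in (
        ("read 1", spectra_set.r1),
        ("read 2", spectra_set.r2),
        ("combined", spectra_set.combined),
    ):
        if not hist:
            continue
        xs = sorted(hist)
        ax.plot(xs, [hist[m] for m in xs], label=label)
    if analysis is not None and analysis.main_peak is not None:
        ax.axvline(analysis.main_peak, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("k-mer multiplicity (coverage)")
    ax.set_ylabel("distinct k-mers")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)


def read_overlay(path: str) -> SpectraSet:
    """Re-read an overlay TSV written by export_overlay (k is not stored)."""
    r1: dict[int, int] = {}
    r2: dict[int, int] = {}
    combined: dict[int, int] = {}
    with open(path, "rt") as handle:
        handle.readline()
        for line in handle:
            m_s, a, b, c = line.rstrip("\n").split("\t")
            m = int(m_s)
            if int(a):
                r1[m] = int(a)
            if int(b):
                r2[m] = int(b)
            if int(c):
                combined[m] = int(c)
    return SpectraSet(k=0, r1=r1, r2=r2, combined=combined)
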