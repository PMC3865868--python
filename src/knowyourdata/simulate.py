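"""Synthetic sequencing data with ground truth for every toolkit analysis.

Generates seeded random genomes (haploid or diploid with a configurable
heterozygous SNP rate), uniform-coverage error-bearing reads, contaminant-
spiked mixtures, Nextera LMP libraries with embedded junction adaptors,
and offset-barcoded RAD reads — each alongside a truth table (a pandas
DataFrame, one row per emitted read or pair) so analyses can be verified
against construction rather than against themselves.

Everything is deterministic under a fixed seed: identical seeds give
byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from knowyourdata.demux import BarcodeSpec
from knowyourdata.io_formats import ReadPair, ReadRecord, reverse_complement
from knowyourdata.matepair import NEXTERA_JUNCTION

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for a simulated run.

    Defaults describe a desk-scale Illumina-like experiment: a 100 kb
    genome at 50x depth with 100-base error-free Q40 reads — enough to
    produce clean k-mer spectra and exact truth recovery while running in
    seconds.
    """

    seed: int = 1
    genome_size: int = 100_000
    gc_fraction: float = 0.5
    ploidy: int = 1
    het_snp_rate: float = 0.0
    read_length: int = 100
    depth: float = 50.0
    substitution_error_rate: float = 0.0
    quality_profile: int | list[int] = 40  # constant phred, or per-cycle list

    def __post_init__(self) -> None:
        for rate_name in ("gc_fraction", "het_snp_rate", "substitution_error_rate"):
            rate = getattr(self, rate_name)
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{rate_name} must be in [0,1], got {rate}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")

    def quality_string(self, length: int) -> str:
        if isinstance(self.quality_profile, int):
            return chr(33 + self.quality_profile) * length
        profile = self.quality_profile
        return "".join(
            chr(33 + profile[min(i, len(profile) - 1)]) for i in range(length)
        )


def sim_genome(config: SimConfig) -> list[str]:
    """Seeded random genome; one sequence per haplotype.

    Base composition converges on gc_fraction; a diploid second haplotype
    differs from the first by Bernoulli(het_snp_rate) substitutions.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    hap1 = "".join(rng.choice(_BASES, size=config.genome_size, p=probs))
    if config.ploidy == 1:
        return [hap1]
    hap2 = list(hap1)
    snp_sites = np.nonzero(rng.random(config.genome_size) < config.het_snp_rate)[0]
    for site in snp_sites.tolist():
        current = hap2[site]
        choices = [b for b in "ACGT" if b != current]
        hap2[site] = choices[rng.integers(0, 3)]
    return [hap1, "".join(hap2)]


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0.0:
        return seq, 0
    n_errors = rng.binomial(len(seq), rate)
    if n_errors == 0:
        return seq, 0
    positions = rng.choice(len(seq), size=n_errors, replace=False)
    out = list(seq)
    for pos in positions.tolist():
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out), n_errors


def sim_reads(
    genome: list[str] | str,
    config: SimConfig,
    paired: bool = False,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    id_prefix: str = "read",
) -> tuple[list[ReadRecord] | list[ReadPair], pd.DataFrame]:
    """Uniform-start reads (or pairs) with substitution errors and truth.

    Read count = round(depth x genome_size / read_length / (2 if paired)).
    Haplotypes of a diploid genome are sampled evenly.  Truth records the
    haplotype, 0-based start, strand and error count of every read.
    """
    haplotypes = [genome] if isinstance(genome, str) else list(genome)
    rng = np.random.default_rng(config.seed + 1)
    length = config.read_length
    if any(length > len(h) for h in haplotypes):
        raise ValueError("read_length exceeds genome size")
    genome_size = len(haplotypes[0])
    n_units = round(config.depth * genome_size / length / (2 if paired else 1))
    truth_rows = []
    out: list = []
    for i in range(n_units):
        hap_index = int(rng.integers(0, len(haplotypes)))
        hap = haplotypes[hap_index]
        if not paired:
            start = int(rng.integers(0, len(hap) - length + 1))
            forward = bool(rng.random() < 0.5)
            seq = hap[start : start + length]
            if not forward:
                seq = reverse_complement(seq)
            seq, n_err = _apply_errors(seq, config.substitution_error_rate, rng)
            out.append(ReadRecord(f"{id_prefix}_{i}", seq, config.quality_string(length)))
            truth_rows.append(
                {
                    "read_id": f"{id_prefix}_{i}",
                    "haplotype": hap_index,
                    "start": start,
                    "strand": "+" if forward else "-",
                    "errors": n_err,
                }
            )
        else:
            insert = max(2 * length, int(round(rng.normal(insert_mean, insert_sd))))
            insert = min(insert, len(hap))
            start = int(rng.integers(0, len(hap) - insert + 1))
            frag = hap[start : start + insert]
            r1_seq, e1 = _apply_errors(frag[:length], config.substitution_error_rate, rng)
            r2_seq, e2 = _apply_errors(
                reverse_complement(frag[-length:]), config.substitution_error_rate, rng
            )
            qual = config.quality_string(length)
            out.append(
                ReadPair(
                    ReadRecord(f"{id_prefix}_{i}/1", r1_seq, qual),
                    ReadRecord(f"{id_prefix}_{i}/2", r2_seq, qual),
                )
            )
            truth_rows.append(
                {
                    "read_id": f"{id_prefix}_{i}",
                    "haplotype": hap_index,
                    "start": start,
                    "insert": insert,
                    "errors": e1 + e2,
                }
            )
    return out, pd.DataFrame(truth_rows)


def spike_contaminant(
    host_reads: list[ReadRecord],
    contaminant_reads: list[ReadRecord],
    fraction: float,
    seed: int = 0,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Mix contaminant reads into a host read set at a target fraction.

    The number of contaminant reads taken is round(fraction x n_host /
    (1 - fraction)), so the contaminant makes up `fraction` of the output.
    Interleaving is a seeded shuffle (deterministic); truth labels every
    read host/contaminant.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    n_spike = round(fraction * len(host_reads) / (1.0 - fraction))
    if n_spike > len(contaminant_reads):
        raise ValueError(
            f"need {n_spike} contaminant reads, have {len(contaminant_reads)}"
        )
    rng = np.random.default_rng(seed)
    labelled = [(r, "host") for r in host_reads] + [
        (r, "contaminant") for r in contaminant_reads[:n_spike]
    ]
    order = rng.permutation(len(labelled))
    mixed = [labelled[i] for i in order.tolist()]
    truth = pd.DataFrame(
        {"read_id": [r.read_id for r, _ in mixed], "origin": [o for _, o in mixed]}
    )
    return [r for r, _ in mixed], truth


def sim_lmp_library(
    genome: str,
    config: SimConfig,
    n_pairs: int = 10_000,
    fragment_mean: float = 3000.0,
    fragment_sd: float = 300.0,
    true_mp_fraction: float = 0.8,
    secondary_mean: float = 450.0,
    secondary_sd: float = 120.0,
    junction: str = NEXTERA_JUNCTION,
    min_overlap: int = 18,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Nextera-style LMP library with construction truth.

    True mate pairs: a large fragment (size ~ Normal(fragment_mean,
    fragment_sd)) is circularized at the junction adaptor and re-fragmented
    into a sequencing molecule of size ~ Normal(secondary_mean,
    secondary_sd) spanning the junction; the junction lands uniformly
    inside it, leaving arms of length a1 (from the fragment's far end,
    read as R1) and a2 (from the fragment's start, read as R2).  A read
    whose arm is shorter than the read length runs through the adaptor at
    position exactly equal to the arm length.  Artefact pairs
    (1 - true_mp_fraction of the library) are ordinary short-insert pairs
    with no junction.

    Truth columns: category (A/B/C/D by adaptor visibility: at least
    min_overlap junction bases must fall inside a read for any
    overlap-based detector to see it), junction_r1/junction_r2 (position
    or -1), arm1/arm2, fragment_size.
    """
    rng = np.random.default_rng(config.seed + 2)
    length = config.read_length
    pairs: list[ReadPair] = []
    truth_rows = []
    for i in range(n_pairs):
        is_true_mp = bool(rng.random() < true_mp_fraction)
        if is_true_mp:
            frag_size = int(
                np.clip(rng.normal(fragment_mean, fragment_sd), 2 * length, len(genome))
            )
            start = int(rng.integers(0, len(genome) - frag_size + 1))
            frag = genome[start : start + frag_size]
            molecule = int(
                np.clip(rng.normal(secondary_mean, secondary_sd), 2 * min_overlap + 2, frag_size)
            )
            arm1 = int(rng.integers(1, molecule))
            arm2 = molecule - arm1
            # The circularization joins frag's end to its start:
            # ... frag[-2] frag[-1] | junction | frag[0] frag[1] ...
            # R1 reads the plus strand into the junction; R2 reads the
            # minus strand from the other side.  The junction therefore
            # starts at read position == arm length in both reads.
            r1_raw = frag[-arm1:] + junction + frag[:length]
            r2_raw = reverse_complement(frag[:arm2]) + junction + reverse_complement(frag[-length:])
            r1_seq = r1_raw[:length]
            r2_seq = r2_raw[:length]
            junction_r1 = arm1 if arm1 + min_overlap <= length else -1
            junction_r2 = arm2 if arm2 + min_overlap <= length else -1
            if junction_r1 >= 0 and junction_r2 >= 0:
                category = "A"
            elif junction_r2 >= 0:
                category = "B"
            elif junction_r1 >= 0:
                category = "C"
            else:
                category = "D"
        else:
            insert = max(2 * length, int(round(rng.normal(300.0, 30.0))))
            start = int(rng.integers(0, len(genome) - insert + 1))
            frag = genome[start : start + insert]
            r1_seq = frag[:length]
            r2_seq = reverse_complement(frag[-length:])
            frag_size = insert
            arm1 = arm2 = -1
            junction_r1 = junction_r2 = -1
            category = "D"
        r1_seq, e1 = _apply_errors(r1_seq, config.substitution_error_rate, rng)
        r2_seq, e2 = _apply_errors(r2_seq, config.substitution_error_rate, rng)
        qual1 = config.quality_string(len(r1_seq))
        qual2 = config.quality_string(len(r2_seq))
        pairs.append(
            ReadPair(
                ReadRecord(f"lmp_{i}/1", r1_seq, qual1),
                ReadRecord(f"lmp_{i}/2", r2_seq, qual2),
            )
        )
        truth_rows.append(
            {
                "read_id": f"lmp_{i}",
                "true_mp": is_true_mp,
                "category": category,
                "junction_r1": junction_r1,
                "junction_r2": junction_r2,
                "arm1": arm1,
                "arm2": arm2,
                "fragment_size": frag_size,
                "errors": e1 + e2,
            }
        )
    return pairs, pd.DataFrame(truth_rows)


def spike_duplicates(
    pairs: list[ReadPair], duplicate_fraction: float, seed: int = 0
) -> list[ReadPair]:
    """Append round(d x n) exact copies of random pairs (PCR duplicates)."""
    rng = np.random.default_rng(seed)
    n_dup = round(duplicate_fraction * len(pairs))
    copies = []
    for j, index in enumerate(rng.integers(0, len(pairs), size=n_dup).tolist()):
        source = pairs[index]
        copies.append(
            ReadPair(
                ReadRecord(f"dup_{j}/1", source.r1.sequence, source.r1.quality),
                ReadRecord(f"dup_{j}/2", source.r2.sequence, source.r2.quality),
            )
        )
    return pairs + copies


def sim_rad_reads(
    genome: str,
    specs: list[BarcodeSpec],
    config: SimConfig,
    n_reads: int = 10_000,
    locus_count: int = 200,
    barcode_errors_per_read: int = 0,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Offset inline-barcoded RAD reads with per-read sample/offset truth.

    Each read = offset filler (random bases) + barcode + overhang +
    genomic sequence from one of locus_count fixed loci, truncated to the
    read length.  Offsets are uniform over each spec's allowed set.
    barcode_errors_per_read substitutions are placed inside the barcode
    only (the overhang must stay intact to anchor the offset).
    """
    rng = np.random.default_rng(config.seed + 3)
    length = config.read_length
    max_prefix = max(
        max(s.allowed_offsets) + len(s.barcode) + len(s.overhang) for s in specs
    )
    loci = rng.integers(0, len(genome) - length - max_prefix + 1, size=locus_count)
    reads: list[ReadRecord] = []
    truth_rows = []
    for i in range(n_reads):
        spec = specs[int(rng.integers(0, len(specs)))]
        offsets = sorted(spec.allowed_offsets)
        offset = offsets[int(rng.integers(0, len(offsets)))]
        locus = int(loci[int(rng.integers(0, locus_count))])
        filler = "".join(rng.choice(_BASES, size=offset)) if offset else ""
        barcode = spec.barcode
        if barcode_errors_per_read > 0:
            bc = list(barcode)
            sites = rng.choice(len(bc), size=barcode_errors_per_read, replace=False)
            for site in sites.tolist():
                bc[site] = [b for b in "ACGT" if b != bc[site]][rng.integers(0, 3)]
            barcode = "".join(bc)
        genomic = genome[locus : locus + length]
        seq = (filler + barcode + spec.overhang + genomic)[:length]
        reads.append(ReadRecord(f"rad_{i}", seq, config.quality_string(len(seq))))
        truth_rows.append(
            {
                "read_id": f"rad_{i}",
                "sample": spec.sample_name,
                "offset": offset,
                "locus": locus,
            }
        )
    return reads, pd.DataFrame(truth_rows)
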