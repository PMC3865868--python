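import numpy as np
import pytest

from knowyourdata.io_formats import AlignedPair, ReadPair, ReadRecord
from knowyourdata.matepair import (
    NEXTERA_JUNCTION,
    AdaptorSpec,
    analyze_library,
    classify_and_clip,
    classify_orientation,
    duplicate_rate,
    find_junction,
    gc_read_histogram,
    orientation_analysis,
)
from knowyourdata.simulate import SimConfig, sim_genome, sim_lmp_library, spike_duplicates


def _read(seq):
    return ReadRecord("r", seq, "I" * len(seq))


def _pair(seq1, seq2):
    return ReadPair(
        ReadRecord("p/1", seq1, "I" * len(seq1)), ReadRecord("p/2", seq2, "I" * len(seq2))
    )


def test_junction_is_its_own_reverse_complement():
    from knowyourdata.io_formats import reverse_complement

    assert reverse_complement(NEXTERA_JUNCTION) == NEXTERA_JUNCTION
    assert len(NEXTERA_JUNCTION) == 38


class TestFindJunction:
    def test_exact_embedded_match(self, small_genome):
        read = _read(small_genome[:30] + NEXTERA_JUNCTION + small_genome[50:60])
        assert find_junction(read) == 30

    def test_prefix_overlap_at_three_prime_end(self, small_genome):
        read = _read(small_genome[:82] + NEXTERA_JUNCTION[:18])
        assert find_junction(read) == 82

    def test_overlap_below_min_overlap_not_found(self, small_genome):
        read = _read(small_genome[:85] + NEXTERA_JUNCTION[:15])
        assert find_junction(read) is None

    def test_mismatch_budget_scales_with_overlap(self, small_genome):
        junction = list(NEXTERA_JUNCTION)
        junction[5] = "A" if junction[5] != "A" else "C"
        junction[20] = "A" if junction[20] != "A" else "C"
        read = _read(small_genome[:40] + "".join(junction) + small_genome[40:50])
        assert find_junction(read) == 40  # 2 mismatches within the 4/38 budget

    def test_too_many_mismatches_rejected(self, small_genome):
        junction = list(NEXTERA_JUNCTION)
        for i in (2, 9, 16, 23, 30):
            junction[i] = "A" if junction[i] != "A" else "C"
        read = _read(small_genome[:40] + "".join(junction) + small_genome[40:50])
        assert find_junction(read) is None

    def test_random_reads_essentially_never_match(self):
        genome = sim_genome(SimConfig(seed=61, genome_size=20_000))[0]
        hits = sum(
            find_junction(_read(genome[i : i + 100])) is not None
            for i in range(0, 10_000, 100)
        )
        assert hits <= 1  # >= 99/100 clean


class TestClassifyAndClip:
    def test_category_a_clips_both(self, small_genome):
        pair = _pair(
            small_genome[:50] + NEXTERA_JUNCTION + small_genome[100:112],
            small_genome[200:260] + NEXTERA_JUNCTION + small_genome[300:302],
        )
        category, clipped = classify_and_clip(pair)
        assert category == "A"
        assert (len(clipped.r1), len(clipped.r2)) == (50, 60)

    def test_category_b_leaves_r1_untouched(self, small_genome):
        pair = _pair(
            small_genome[:100],
            small_genome[200:240] + NEXTERA_JUNCTION + small_genome[300:322],
        )
        category, clipped = classify_and_clip(pair)
        assert category == "B"
        assert clipped.r1.sequence == pair.r1.sequence
        assert len(clipped.r2) == 40

    def test_short_clip_excluded_but_categorized(self, small_genome):
        pair = _pair(
            small_genome[:10] + NEXTERA_JUNCTION + small_genome[100:152],
            small_genome[200:300],
        )
        category, clipped = classify_and_clip(pair, min_length=25)
        assert category == "C"
        assert clipped is None

    def test_simulated_library_truth_recovery(self, small_genome):
        config = SimConfig(seed=62)
        pairs, truth = sim_lmp_library(small_genome, config, n_pairs=500)
        for pair, row in zip(pairs, truth.itertuples()):
            category, clipped = classify_and_clip(pair)
            assert category == row.category
            if clipped is not None:
                if row.junction_r1 >= 0:
                    assert len(clipped.r1) == row.junction_r1 == row.arm1
                if row.junction_r2 >= 0:
                    assert len(clipped.r2) == row.junction_r2 == row.arm2

    def test_category_counts_sum_to_input(self, small_genome):
        config = SimConfig(seed=63)
        pairs, _ = sim_lmp_library(small_genome, config, n_pairs=300)
        report = analyze_library(pairs)
        assert sum(report.category_counts.values()) == report.total_pairs == 300


class TestDuplicateRate:
    def test_spiked_copies_arithmetic(self, small_genome):
        pairs = [
            _pair(small_genome[i : i + 50], small_genome[i + 60 : i + 110])
            for i in range(0, 5000, 50)
        ]
        duplicated = pairs + [pairs[0]] * 10
        rate, considered, skipped = duplicate_rate(duplicated)
        assert rate == pytest.approx(100.0 * (1 - 100 / 110))
        assert considered == 110 and skipped == 0

    def test_all_distinct_zero(self, small_genome):
        pairs = [
            _pair(small_genome[i : i + 50], small_genome[i + 60 : i + 110])
            for i in range(0, 2000, 50)
        ]
        assert duplicate_rate(pairs)[0] == 0.0

    def test_all_identical_closed_form(self, small_genome):
        pair = _pair(small_genome[:50], small_genome[60:110])
        rate, _, _ = duplicate_rate([pair] * 8)
        assert rate == pytest.approx(100.0 * (1 - 1 / 8))

    def test_short_reads_skipped_and_counted(self, small_genome):
        pairs = [
            _pair(small_genome[:50], small_genome[60:110]),
            _pair("ACGT", "ACGT"),
        ]
        rate, considered, skipped = duplicate_rate(pairs, signature_bases=16)
        assert considered == 1 and skipped == 1

    def test_simulator_duplicate_spike_closed_form(self, small_genome):
        config = SimConfig(seed=64)
        pairs, _ = sim_lmp_library(small_genome, config, n_pairs=1000)
        spiked = spike_duplicates(pairs, 0.1, seed=65)
        rate, considered, _ = duplicate_rate(spiked)
        assert considered == 1100
        assert rate == pytest.approx(100.0 * 0.1 / 1.1, abs=1e-9)


class TestGcHistogram:
    @pytest.mark.parametrize(
        "seq,expected_bin",
        [("GGCC", 100), ("ACGT", 50), ("ANGT", 33), ("AATT", 0)],
    )
    def test_gc_binning(self, seq, expected_bin):
        hist, skipped = gc_read_histogram([seq])
        assert hist == {expected_bin: 1}
        assert skipped == 0

    def test_all_n_read_skipped(self):
        hist, skipped = gc_read_histogram(["NNNN"])
        assert hist == {} and skipped == 1


class TestOrientation:
    def _aligned(self, pos1, strand1, pos2, strand2, alen=50):
        return AlignedPair(
            name="q", ref_name1="ref", ref_name2="ref",
            pos1=pos1, pos2=pos2, strand1=strand1, strand2=strand2,
            alen1=alen, alen2=alen, mapped1=True, mapped2=True,
        )

    def test_inward_is_paired_end_with_outer_span(self):
        orientation, insert = classify_orientation(self._aligned(100, "+", 1000, "-"))
        assert orientation == "paired_end"
        assert insert == 950  # 1049 - 100 + 1

    def test_outward_is_mate_pair(self):
        orientation, _ = classify_orientation(self._aligned(100, "-", 1000, "+"))
        assert orientation == "mate_pair"

    def test_same_strand_is_tandem(self):
        orientation, _ = classify_orientation(self._aligned(100, "+", 1000, "+"))
        assert orientation == "tandem"

    def test_cross_reference_and_unmapped_are_discordant(self):
        cross = AlignedPair(
            name="q", ref_name1="ref", ref_name2="other",
            pos1=1, pos2=1, strand1="+", strand2="-",
            alen1=50, alen2=50, mapped1=True, mapped2=True,
        )
        report = orientation_analysis([cross])
        assert report.discordant == 1 and not report.insert_histograms

    def test_histograms_keyed_per_orientation(self):
        pairs = [
            self._aligned(100, "+", 1000, "-"),
            self._aligned(200, "-", 2000, "+"),
            self._aligned(10, "+", 500, "+"),
        ]
        report = orientation_analysis(pairs)
        assert set(report.insert_histograms) == {"paired_end", "mate_pair", "tandem"}

    def test_insert_distribution_mean_matches_construction(self):
        rng = np.random.default_rng(66)
        inserts = rng.normal(3000, 300, size=500).astype(int)
        pairs = [
            self._aligned(100, "-", 100 + int(ins) - 50, "+")
            for ins in inserts
        ]
        report = orientation_analysis(pairs)
        hist = report.insert_histograms["mate_pair"]
        observed = sum(m * c for m, c in hist.items()) / sum(hist.values())
        assert abs(observed - inserts.mean()) / inserts.mean() < 0.02
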