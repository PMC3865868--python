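import pytest

from knowyourdata.contamination import (
    ScreenReport,
    build_reference_table,
    filter_reads,
    interpret_screen,
    screen_reads,
    write_screen_reports,
)
from knowyourdata.io_formats import ReadRecord, ReadPair, write_fasta
from knowyourdata.kmer_core import SubsampleSpec, count_kmers
from knowyourdata.simulate import SimConfig, sim_genome, sim_reads, spike_contaminant


def _as_reads(seqs, prefix="r"):
    return [ReadRecord(f"{prefix}{i}", s, "I" * len(s)) for i, s in enumerate(seqs)]


class TestBuildReferenceTable:
    def test_unique_sequence_kmer_count(self, tmp_path, small_genome):
        # a 100 bp unique-kmer sequence yields L-k+1 distinct 21-mers
        seq = small_genome[:100]
        path = write_fasta([("c", seq)], tmp_path / "ref.fasta")
        table = build_reference_table(path, 21)
        assert len(table) == 80

    def test_reverse_complement_record_changes_nothing(self, tmp_path, small_genome):
        from knowyourdata.io_formats import reverse_complement

        seq = small_genome[:300]
        single = write_fasta([("c", seq)], tmp_path / "one.fasta")
        both = write_fasta(
            [("c", seq), ("rc", reverse_complement(seq))], tmp_path / "two.fasta"
        )
        t1 = build_reference_table(single, 21)
        t2 = build_reference_table(both, 21)
        assert set(t1.counts) == set(t2.counts)

    def test_homopolymer_single_kmer(self, tmp_path):
        path = write_fasta([("polyA", "A" * 100)], tmp_path / "a.fasta")
        assert len(build_reference_table(path, 21)) == 1

    def test_empty_fasta_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="empty FASTA"):
            build_reference_table(path, 21)


class TestScreenReads:
    def test_reads_from_reference_hit_100_pct(self, small_genome):
        reads = _as_reads([small_genome[i : i + 60] for i in range(0, 2000, 20)])
        table = count_kmers([small_genome], 21)
        report = screen_reads(reads, table, SubsampleSpec(fraction=1.0))
        assert report.reads_with_hit_pct == 100.0

    def test_unrelated_random_genomes_nearly_no_hits(self):
        host = sim_genome(SimConfig(seed=31, genome_size=50_000))[0]
        other = sim_genome(SimConfig(seed=32, genome_size=50_000))[0]
        reads = _as_reads([host[i : i + 100] for i in range(0, 40_000, 100)])
        table = count_kmers([other], 21)
        report = screen_reads(reads, table, SubsampleSpec(fraction=1.0))
        assert report.reads_with_hit_pct < 1.0
        assert report.ref_covered_pct < 1.0

    def test_tiling_reads_cover_reference_fully(self, small_genome):
        ref = small_genome[:2000]
        reads = _as_reads(
            [ref[i : i + 100] for i in range(0, len(ref) - 99, 20)] * 5
        )
        table = count_kmers([ref], 21)
        report = screen_reads(reads, table, SubsampleSpec(fraction=1.0))
        assert report.ref_covered_pct == 100.0

    def test_zero_sampled_reads_is_error(self, small_genome):
        table = count_kmers([small_genome[:100]], 21)
        with pytest.raises(ValueError, match="no reads sampled"):
            screen_reads([], table)

    def test_percentages_consistent_with_counts(self, small_genome):
        reads = _as_reads([small_genome[i : i + 50] for i in range(0, 3000, 30)])
        table = count_kmers([small_genome[:1000]], 21)
        report = screen_reads(reads, table, SubsampleSpec(fraction=1.0))
        assert report.reads_with_hit_pct == pytest.approx(
            100.0 * report.reads_with_hit / report.reads_screened, abs=1e-4
        )
        assert report.ref_covered_pct == pytest.approx(
            100.0 * report.ref_kmers_observed / report.ref_kmers_total, abs=1e-4
        )


class TestInterpretScreen:
    def _report(self, hit, cov):
        return ScreenReport("ref", 21, 1000, 0, hit, 1000, 0, cov, 1.0)

    @pytest.mark.parametrize(
        "hit,cov,expected",
        [
            (40.0, 85.0, "true_contamination"),
            (12.0, 0.8, "shared_kmers_only"),  # the E. coli-style signature
            (0.1, 0.05, "clean"),
            (5.0, 20.0, "true_contamination"),  # thresholds inclusive
        ],
    )
    def test_rule(self, hit, cov, expected):
        assert interpret_screen(self._report(hit, cov), 5.0, 20.0) == expected

    def test_threshold_bounds_checked(self):
        with pytest.raises(ValueError):
            interpret_screen(self._report(1, 1), -5, 20)


@pytest.fixture(scope="module")
def spiked():
    host_cfg = SimConfig(seed=41, genome_size=50_000, depth=5)
    cont_cfg = SimConfig(seed=42, genome_size=10_000, depth=20)
    host = sim_genome(host_cfg)[0]
    cont = sim_genome(cont_cfg)[0]
    host_reads, _ = sim_reads(host, host_cfg, id_prefix="host")
    cont_reads, _ = sim_reads(cont, cont_cfg, id_prefix="cont")
    mixed, truth = spike_contaminant(host_reads, cont_reads, 0.10, seed=43)
    table = count_kmers([cont], 21)
    host_table = count_kmers([host], 21)
    # precondition of exact recovery: contaminant shares no kmers with host
    assert not set(table.counts) & set(host_table.counts)
    return mixed, truth, table



class TestFilterReads:
    def test_discard_hits_removes_exactly_the_spiked_set(self, spiked):
        mixed, truth, table = spiked
        kept, removed, summary = filter_reads(iter(mixed), table, "discard_hits")
        assert {r.read_id for r in removed} == set(
            truth[truth.origin == "contaminant"].read_id
        )
        assert summary.kept + summary.removed == summary.total == len(mixed)

    def test_mode_symmetry(self, spiked):
        mixed, _, table = spiked
        kept_d, removed_d, _ = filter_reads(iter(mixed), table, "discard_hits")
        kept_k, removed_k, _ = filter_reads(iter(mixed), table, "keep_hits")
        assert [r.read_id for r in kept_d] == [r.read_id for r in removed_k]
        assert [r.read_id for r in removed_d] == [r.read_id for r in kept_k]

    def test_clean_reads_nothing_removed(self, small_genome):
        reads = _as_reads([small_genome[i : i + 60] for i in range(0, 2000, 60)])
        other = sim_genome(SimConfig(seed=44, genome_size=10_000))[0]
        table = count_kmers([other], 21)
        _, removed, _ = filter_reads(iter(reads), table, "discard_hits")
        assert removed == []

    def test_pair_removed_when_either_mate_hits(self, small_genome):
        clean = small_genome[:100]
        other = sim_genome(SimConfig(seed=45, genome_size=10_000))[0]
        dirty = other[:100]
        qual = "I" * 100
        pairs = [
            ReadPair(ReadRecord("p1/1", clean, qual), ReadRecord("p1/2", dirty, qual)),
            ReadPair(ReadRecord("p2/1", clean, qual), ReadRecord("p2/2", clean, qual)),
        ]
        table = count_kmers([other], 21)
        kept, removed, _ = filter_reads(pairs, table, "discard_hits")
        assert [p.stem for p in removed] == ["p1"]
        assert [p.stem for p in kept] == ["p2"]


def test_report_tsv_and_json_round_trip(tmp_path, small_genome):
    import json

    reads = _as_reads([small_genome[i : i + 60] for i in range(0, 600, 60)])
    table = count_kmers([small_genome[:500]], 21)
    report = screen_reads(reads, table, SubsampleSpec(fraction=1.0))
    tsv = tmp_path / "screen.tsv"
    js = tmp_path / "screen.json"
    write_screen_reports([report], tsv, js)
    assert tsv.read_text().startswith("reference\t")
    [payload] = json.loads(js.read_text())
    assert payload["reads_with_hit_pct"] == report.reads_with_hit_pct
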