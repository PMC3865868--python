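import numpy as np
import pytest

from knowyourdata.metricstore import (
    MetricRecord,
    MetricStore,
    RunKey,
    parse_fastqc_report,
    parse_toolkit_reports,
)

KEY = RunKey(run_alias="run1", instrument="HS1", sample="sampleA", lane=1)


class TestRecordInvariants:
    def test_run_scope_rejects_positions(self):
        with pytest.raises(ValueError):
            MetricRecord(KEY, "m", "run", 1.0, position_from=1, position_to=1)

    def test_range_from_greater_than_to_rejected(self):
        with pytest.raises(ValueError):
            MetricRecord(KEY, "m", "range", 1.0, position_from=5, position_to=2)

    def test_base_scope_needs_equal_positions(self):
        with pytest.raises(ValueError):
            MetricRecord(KEY, "m", "base", 1.0, position_from=1, position_to=2)


class TestPutAndQuery:
    def test_idempotent_upsert_single_row(self):
        with MetricStore() as store:
            record = MetricRecord(KEY, "q30_read_pct", "run", 91.5)
            assert store.put_metrics([record]) == 1
            assert store.put_metrics([record]) == 1
            assert len(store.query(name="q30_read_pct")) == 1

    def test_round_trip_values_exact(self):
        rng = np.random.default_rng(90)
        records = []
        for i in range(10_000):
            scope = ("run", "base", "range")[i % 3]
            pos_from = None if scope == "run" else (i % 100) + 1
            pos_to = None if scope == "run" else pos_from + (5 if scope == "range" else 0)
            value = float(rng.normal()) if i % 4 else f"text-{i}"
            records.append(
                MetricRecord(
                    RunKey(run_alias=f"run{i % 7}", lane=i % 4, sample=f"s{i % 11}"),
                    f"metric{i % 50}",
                    scope,
                    value,
                    position_from=pos_from,
                    position_to=pos_to,
                )
            )
        with MetricStore() as store:
            store.put_metrics(records)
            fetched = store.query()
            assert set(fetched) == set(records)

    def test_filter_by_lane(self):
        with MetricStore() as store:
            store.put_metrics(
                [
                    MetricRecord(RunKey("r", lane=1), "m", "run", 1.0),
                    MetricRecord(RunKey("r", lane=2), "m", "run", 2.0),
                ]
            )
            got = store.query(filters={"lane": 1})
            assert len(got) == 1 and got[0].value == 1.0

    def test_absent_metric_empty_not_error(self):
        with MetricStore() as store:
            assert store.query(name="nope") == []

    def test_persistence_to_file(self, tmp_path):
        path = str(tmp_path / "store.sqlite")
        with MetricStore(path) as store:
            store.put_metrics([MetricRecord(KEY, "m", "run", 3.25)])
        with MetricStore(path) as store:
            assert store.query(name="m")[0].value == 3.25


class TestAggregation:
    def test_group_mean(self):
        with MetricStore() as store:
            store.put_metrics(
                [
                    MetricRecord(RunKey("a", instrument="HS1"), "q30", "run", 80.0),
                    MetricRecord(RunKey("b", instrument="HS1"), "q30", "run", 90.0),
                ]
            )
            table = store.aggregate("q30", group_by="instrument")
            row = table.iloc[0]
            assert (row["mean"], row["n"]) == (85.0, 2)

    def test_aggregate_text_rejected(self):
        with MetricStore() as store:
            store.put_metrics([MetricRecord(KEY, "status", "run", "pass")])
            with pytest.raises(TypeError):
                store.aggregate("status")

    def test_aggregation_equals_brute_force_on_random_stores(self):
        rng = np.random.default_rng(91)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            instruments = [f"I{int(rng.integers(0, 3))}" for _ in range(n)]
            values = rng.normal(size=n)
            records = [
                MetricRecord(
                    RunKey(f"r{j}", instrument=instruments[j]), "m", "run", float(values[j])
                )
                for j in range(n)
            ]
            with MetricStore() as store:
                store.put_metrics(records)
                table = store.aggregate("m", group_by="instrument").set_index("group")
            for instrument in set(instruments):
                subset = [v for i, v in zip(instruments, values) if i == instrument]
                assert table.loc[instrument, "mean"] == pytest.approx(np.mean(subset))
                assert table.loc[instrument, "min"] == pytest.approx(np.min(subset))
                assert table.loc[instrument, "max"] == pytest.approx(np.max(subset))
                assert table.loc[instrument, "n"] == len(subset)


FASTQC_TEXT = """##FastQC\t0.11.9
>>Basic Statistics\tpass
#Measure\tValue
Filename\treads.fastq
Total Sequences\t20000
%GC\t48
>>END_MODULE
>>Per base sequence quality\tpass
#Base\tMean\tMedian\tLower Quartile\tUpper Quartile
1\t32.1\t33.0\t31.0\t34.0
2\t32.0\t33.0\t31.0\t34.0
10-14\t30.0\t31.0\t29.0\t32.0
>>END_MODULE
>>Per sequence GC content\twarn
#GC Content\tCount
40\t120.0
41\t150.0
>>END_MODULE
"""


class TestFastqcParser:
    def test_scopes_and_values(self):
        records = parse_fastqc_report(FASTQC_TEXT, KEY)
        by_name = {}
        for rec in records:
            by_name.setdefault(rec.name, []).append(rec)
        assert by_name["total_sequences"][0].scope == "run"
        assert by_name["total_sequences"][0].value == 20000
        base1 = [r for r in by_name["mean_quality"] if r.position_from == 1]
        assert base1[0].scope == "base" and base1[0].value == 32.1
        ranged = [r for r in by_name["mean_quality"] if r.scope == "range"]
        assert (ranged[0].position_from, ranged[0].position_to) == (10, 14)
        assert by_name["per_base_sequence_quality_status"][0].value == "pass"
        assert by_name["gc_content_40"][0].value == 120.0

    def test_row_conservation_per_base_block(self):
        records = parse_fastqc_report(FASTQC_TEXT, KEY)
        per_base = [r for r in records if r.name in (
            "mean_quality", "median_quality", "lower_quartile", "upper_quartile")]
        # 3 data rows x 4 columns
        assert len(per_base) == 12

    def test_missing_end_module_is_error(self):
        broken = ">>Basic Statistics\tpass\nTotal Sequences\t5\n"
        with pytest.raises(ValueError, match="Basic Statistics"):
            parse_fastqc_report(broken, KEY)


class TestToolkitReportParser:
    def test_screen_report_scalars(self):
        payload = {
            "report_type": "screen",
            "reference_name": "ecoli",
            "reads_with_hit_pct": 12.0,
            "ref_covered_pct": 0.8,
        }
        records = parse_toolkit_reports([payload], KEY)
        values = {r.name: r.value for r in records}
        assert values["screen_reads_with_hit_pct"] == 12.0
        assert values["screen_ref_covered_pct"] == 0.8
        assert values["screen_reference_name"] == "ecoli"

    def test_histograms_become_base_series(self):
        payload = {"report_type": "spectra_overlay", "combined": {"1": 50, "2": 30}}
        records = parse_toolkit_reports([payload], KEY)
        assert {(r.scope, r.position_from, r.value) for r in records} == {
            ("base", 1, 50), ("base", 2, 30)
        }

    def test_missing_report_type_rejected(self):
        with pytest.raises(ValueError, match="report_type"):
            parse_toolkit_reports([{"x": 1}], KEY)

    def test_empty_report_zero_records(self):
        assert parse_toolkit_reports([{"report_type": "screen"}], KEY) == []
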