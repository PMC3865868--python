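"""Primary-analysis pipeline driver.

Chains the analytic stages over one sample — read metrics, contamination
screening against every configured reference, optional k-mer spectra, an
MD5 manifest of the inputs — writes every report to the run directory,
and loads all metrics into the metric store.  Red flags never change the
exit status (they are reported for humans to act on); a stage failure
does, with the stage named in the log.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

from knowyourdata import io_formats
from knowyourdata.config import PipelineConfig
from knowyourdata.contamination import (
    ScreenReport,
    build_reference_table,
    interpret_screen,
    screen_reads,
    write_screen_reports,
)
from knowyourdata.kmer_core import SubsampleSpec, load_table
from knowyourdata.metricstore import MetricStore, RunKey, parse_toolkit_reports
from knowyourdata.readmetrics import q30_summary, per_base_quality, summarize_run
from knowyourdata.spectra import analyze_spectrum, compute_spectra, export_overlay

logger = logging.getLogger("knowyourdata.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    exit_status: int
    reports: dict[str, str] = field(default_factory=dict)
    failed_stage: str | None = None


def run_pipeline(
    r1_path: str,
    r2_path: str | None,
    references: dict[str, str],
    config: PipelineConfig,
    output_dir: str,
    run_key: RunKey | None = None,
    with_spectra: bool = False,
) -> PipelineResult:
    """Execute metrics -> screen (per reference) -> [spectra] -> manifest.

    `references` maps reference name -> FASTA path or pre-built k-mer
    table path (detected by the table header).  All reports land in
    output_dir; all metrics are loaded into the store at
    config.store_path.  Returns exit status 0 on success, 2 on a stage
    failure (with the stage named).
    """
    os.makedirs(output_dir, exist_ok=True)
    run_key = run_key or RunKey(run_alias=os.path.basename(output_dir) or "run")
    result = PipelineResult(exit_status=0)
    json_reports: list[dict] = []

    def _stage(name: str, fn):
        logger.info("stage %s: start", name)
        try:
            value = fn()
        except Exception as exc:
            logger.error("stage %s: FAILED: %s", name, exc)
            raise StageError(name, exc) from exc
        logger.info("stage %s: done", name)
        return value

    try:
        summary = _stage("metrics", lambda: _metrics_stage(r1_path, r2_path, config, output_dir))
        json_reports.append(json.loads(summary))
        result.reports["metrics"] = os.path.join(output_dir, "readmetrics.json")

        screen_json = _stage(
            "screen", lambda: _screen_stage(r1_path, r2_path, references, config, output_dir)
        )
        json_reports.extend(screen_json)
        result.reports["screen"] = os.path.join(output_dir, "screen.json")

        if with_spectra:
            spectra_json = _stage(
                "spectra", lambda: _spectra_stage(r1_path, r2_path, config, output_dir)
            )
            json_reports.append(spectra_json)
            result.reports["spectra"] = os.path.join(output_dir, "spectra.json")

        manifest = _stage("manifest", lambda: _manifest_stage(r1_path, r2_path, output_dir))
        result.reports["manifest"] = manifest

        _stage("store", lambda: _store_stage(json_reports, run_key, config))
    except StageError as exc:
        result.exit_status = 2
        result.failed_stage = exc.stage
    return result


def _metrics_stage(
    r1_path: str, r2_path: str | None, config: PipelineConfig, output_dir: str
) -> str:
    summary = q30_summary(io_formats.parse_fastq(r1_path))
    summary = summarize_run(summary, config.thresholds)
    pbq = per_base_quality(io_formats.parse_fastq(r1_path))
    pbq.to_tsv(os.path.join(output_dir, "per_base_quality.tsv"))
    text = summary.to_json()
    with open(os.path.join(output_dir, "readmetrics.json"), "wt") as handle:
        handle.write(text + "\n")
    with open(os.path.join(output_dir, "readmetrics.txt"), "wt") as handle:
        handle.write(summary.to_text() + "\n")
    if r2_path is not None:
        summary2 = summarize_run(q30_summary(io_formats.parse_fastq(r2_path)), config.thresholds)
        with open(os.path.join(output_dir, "readmetrics_r2.json"), "wt") as handle:
            handle.write(summary2.to_json() + "\n")
    return text


def _load_reference(name: str, path: str, k: int):
    with open(path, "rt") as handle:
        first = handle.readline()
    if first.startswith("#knowyourdata kmer-table"):
        return load_table(path, expect_k=k)
    return build_reference_table(path, k)


def _screen_stage(
    r1_path: str,
    r2_path: str | None,
    references: dict[str, str],
    config: PipelineConfig,
    output_dir: str,
) -> list[dict]:
    subsample = SubsampleSpec(
        fraction=config.subsample_fraction,
        mode=config.subsample_mode,
        seed=config.seed,
    )
    reports: list[ScreenReport] = []
    for name, path in references.items():
        table = _load_reference(name, path, config.k_screen)

        def reads():
            yield from io_formats.parse_fastq(r1_path)
            if r2_path is not None:
                yield from io_formats.parse_fastq(r2_path)

        report = screen_reads(reads(), table, subsample, reference_name=name)
        reports.append(report)
        logger.info(
            "screen %s: hit %.4f%%, coverage %.4f%% -> %s",
            name,
            report.reads_with_hit_pct,
            report.ref_covered_pct,
            interpret_screen(
                report, config.read_hit_threshold_pct, config.coverage_threshold_pct
            ),
        )
    write_screen_reports(
        reports,
        os.path.join(output_dir, "screen.tsv"),
        os.path.join(output_dir, "screen.json"),
    )
    return [{"report_type": "screen", **asdict(r)} for r in reports]


def _spectra_stage(
    r1_path: str, r2_path: str | None, config: PipelineConfig, output_dir: str
) -> dict:
    spectra_set = compute_spectra(
        io_formats.parse_fastq(r1_path),
        io_formats.parse_fastq(r2_path) if r2_path else None,
        k=config.k_spectra,
    )
    analysis = analyze_spectrum(
        spectra_set.combined, config.smoothing_window, config.het_tolerance
    )
    export_overlay(spectra_set, os.path.join(output_dir, "spectra_overlay.tsv"), analysis)
    with open(os.path.join(output_dir, "spectra.json"), "wt") as handle:
        handle.write(analysis.to_json() + "\n")
    return json.loads(analysis.to_json())


def _manifest_stage(r1_path: str, r2_path: str | None, output_dir: str) -> str:
    paths = [r1_path] + ([r2_path] if r2_path else [])
    manifest_path = os.path.join(output_dir, "manifest.md5")
    io_formats.md5_manifest(paths, manifest_path)
    return manifest_path


def _store_stage(json_reports: list[dict], run_key: RunKey, config: PipelineConfig) -> int:
    records = parse_toolkit_reports(json_reports, run_key)
    with MetricStore(config.store_path) as store:
        return store.put_metrics(records)
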