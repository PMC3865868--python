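"""Embedded QC metric store with per-run / per-base / per-range scoping.

The store keeps any run metric or metadata in a single-file SQLite
database.  Every metric is scoped either to a whole run, to a single base
position, or to an inclusive base range (e.g. bases 1-5), and is keyed by
the run's identity (run alias, instrument, chemistry and software
versions, lane, sample, barcode).  Parsers ingest FastQC ``fastqc_data.txt``
reports and this toolkit's own JSON reports; consumers query with filters
and cross-run group-by aggregation, which is what makes lane-, instrument-
and time-level comparisons possible at all.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field, asdict
from typing import Any, Iterable

import pandas as pd

SCOPES = ("run", "base", "range")


@dataclass(frozen=True)
class RunKey:
    """Identity of one sequenced sample within a run."""

    run_alias: str
    instrument: str = ""
    chemistry_version: str = ""
    software_version: str = ""
    lane: int | None = None
    sample: str = ""
    barcode: str | None = None


@dataclass(frozen=True)
class MetricRecord:
    """A named QC value scoped to a run, one base, or a base range."""

    key: RunKey
    name: str
    scope: str
    value: float | int | str
    position_from: int | None = None
    position_to: int | None = None

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}, got {self.scope!r}")
        if self.scope == "run":
            if self.position_from is not None or self.position_to is not None:
                raise ValueError("run-scope records carry no positions")
        else:
            if self.position_from is None or self.position_to is None:
                raise ValueError(f"{self.scope}-scope records need positions")
            if self.position_from < 1:
                raise ValueError("positions are 1-based")
            if self.scope == "base" and self.position_from != self.position_to:
                raise ValueError("base-scope records need position_from == position_to")
            if self.position_from > self.position_to:
                raise ValueError("position_from must be <= position_to")


# SQLite treats NULLs in a primary key as pairwise distinct, which would
# defeat the idempotent upsert; optional fields use sentinels instead
# (lane -1, barcode '', positions 0) and are mapped back to None on read.
_SCHEMA = """
CREATE TABLE IF NOT EXISTS metrics (
    run_alias TEXT NOT NULL,
    instrument TEXT NOT NULL DEFAULT '',
    chemistry_version TEXT NOT NULL DEFAULT '',
    software_version TEXT NOT NULL DEFAULT '',
    lane INTEGER NOT NULL DEFAULT -1,
    sample TEXT NOT NULL DEFAULT '',
    barcode TEXT NOT NULL DEFAULT '',
    name TEXT NOT NULL,
    scope TEXT NOT NULL CHECK (scope IN ('run','base','range')),
    position_from INTEGER NOT NULL DEFAULT 0,
    position_to INTEGER NOT NULL DEFAULT 0,
    value_num REAL,
    value_text TEXT,
    PRIMARY KEY (run_alias, lane, sample, barcode, name, scope,
                 position_from, position_to)
);
"""


class MetricStore:
    """Single-file metric warehouse; use as a context manager or close()."""

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self._conn = sqlite3.connect(path)
        self._conn.execute(_SCHEMA)
        self._conn.commit()

    def __enter__(self) -> "MetricStore":
        return self

    def __exit__(self, *exc: Any) -> None:
        self.close()

    def close(self) -> None:
        self._conn.close()

    def put_metrics(self, records: Iterable[MetricRecord]) -> int:
        """Idempotent upsert on (key, name, scope, positions); returns count."""
        rows = []
        for index, rec in enumerate(records):
            if not isinstance(rec, MetricRecord):
                raise TypeError(f"record {index} is not a MetricRecord")
            numeric = isinstance(rec.value, (int, float)) and not isinstance(rec.value, bool)
            rows.append(
                (
                    rec.key.run_alias,
                    rec.key.instrument,
                    rec.key.chemistry_version,
                    rec.key.software_version,
                    -1 if rec.key.lane is None else rec.key.lane,
                    rec.key.sample,
                    "" if rec.key.barcode is None else rec.key.barcode,
                    rec.name,
                    rec.scope,
                    0 if rec.position_from is None else rec.position_from,
                    0 if rec.position_to is None else rec.position_to,
                    float(rec.value) if numeric else None,
                    None if numeric else str(rec.value),
                )
            )
        self._conn.executemany(
            """INSERT INTO metrics VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?)
               ON CONFLICT DO UPDATE SET
                 instrument=excluded.instrument,
                 chemistry_version=excluded.chemistry_version,
                 software_version=excluded.software_version,
                 value_num=excluded.value_num,
                 value_text=excluded.value_text""",
            rows,
        )
        self._conn.commit()
        return len(rows)

    def query(
        self,
        filters: dict[str, Any] | None = None,
        name: str | None = None,
        scope: str | None = None,
    ) -> list[MetricRecord]:
        """Records matching exact filters on RunKey fields / name / scope."""
        clauses: list[str] = []
        params: list[Any] = []
        for column, value in (filters or {}).items():
            if value is None:
                value = -1 if column == "lane" else ""
            clauses.append(f"{column} = ?")
            params.append(value)
        if name is not None:
            clauses.append("name = ?")
            params.append(name)
        if scope is not None:
            clauses.append("scope = ?")
            params.append(scope)
        sql = "SELECT * FROM metrics"
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY run_alias, name, scope, position_from"
        records = []
        for row in self._conn.execute(sql, params):
            (
                run_alias, instrument, chemistry, software, lane, sample, barcode,
                metric_name, metric_scope, pos_from, pos_to, value_num, value_text,
            ) = row
            value: float | str = value_num if value_text is None else value_text
            records.append(
                MetricRecord(
                    key=RunKey(
                        run_alias,
                        instrument,
                        chemistry,
                        software,
                        None if lane == -1 else lane,
                        sample,
                        barcode or None,
                    ),
                    name=metric_name,
                    scope=metric_scope,
                    value=value,
                    position_from=pos_from or None,
                    position_to=pos_to or None,
                )
            )
        return records

    def aggregate(
        self,
        name: str,
        group_by: str = "instrument",
        filters: dict[str, Any] | None = None,
    ) -> pd.DataFrame:
        """Cross-run consolidation: mean/min/max/n of a numeric metric.

        Raises if any matching record holds a text value — aggregating text
        is a caller error, not a silent NaN.
        """
        records = self.query(filters=filters, name=name)
        if any(isinstance(r.value, str) for r in records):
            raise TypeError(f"metric {name!r} holds text values; cannot aggregate")
        frame = pd.DataFrame(
            {
                "group": [getattr(r.key, group_by) for r in records],
                "value": [r.value for r in records],
            }
        )
        if frame.empty:
            return pd.DataFrame(columns=["group", "mean", "min", "max", "n"])
        out = (
            frame.groupby("group")["value"]
            .agg(mean="mean", min="min", max="max", n="count")
            .reset_index()
        )
        return out


def parse_fastqc_report(text: str, key: RunKey) -> list[MetricRecord]:
    """Parse a ``fastqc_data.txt`` report into scoped metric records.

    Modules are delimited ``>>Module Name<TAB>status`` ... ``>>END_MODULE``.
    Basic Statistics rows become run-scope records; Per base sequence
    quality rows become base-scope (cycle "10") or range-scope (cycle
    "10-14") records named mean_quality/median_quality/...; Per sequence GC
    content rows become run-scope histogram records; every module's
    pass/warn/fail status is stored as a run-scope text record.
    """
    records: list[MetricRecord] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(">>") and not line.startswith(">>END_MODULE"):
            header = line[2:]
            module, _, status = header.partition("\t")
            rows: list[list[str]] = []
            i += 1
            closed = False
            while i < len(lines):
                if lines[i].startswith(">>END_MODULE"):
                    closed = True
                    break
                if not lines[i].startswith("#") and lines[i].strip():
                    rows.append(lines[i].split("\t"))
                i += 1
            if not closed:
                raise ValueError(f"module {module!r} missing >>END_MODULE")
            slug = module.lower().replace(" ", "_")
            records.append(
                MetricRecord(key=key, name=f"{slug}_status", scope="run", value=status)
            )
            records.extend(_fastqc_module_records(module, slug, rows, key))
        i += 1
    return records


def _parse_positions(token: str) -> tuple[int, int, str]:
    if "-" in token:
        lo, hi = token.split("-")
        return int(lo), int(hi), "range"
    pos = int(token)
    return pos, pos, "base"


def _maybe_number(token: str) -> float | str:
    try:
        return float(token)
    except ValueError:
        return token


_PER_BASE_COLUMNS = ("mean_quality", "median_quality", "lower_quartile", "upper_quartile")


def _fastqc_module_records(
    module: str, slug: str, rows: list[list[str]], key: RunKey
) -> list[MetricRecord]:
    records: list[MetricRecord] = []
    if module == "Basic Statistics":
        for row in rows:
            if len(row) < 2:
                continue
            name = row[0].lower().replace(" ", "_")
            records.append(
                MetricRecord(key=key, name=name, scope="run", value=_maybe_number(row[1]))
            )
    elif module == "Per base sequence quality":
        for row in rows:
            lo, hi, scope = _parse_positions(row[0])
            for col, name in enumerate(_PER_BASE_COLUMNS, start=1):
                if col < len(row):
                    records.append(
                        MetricRecord(
                            key=key,
                            name=name,
                            scope=scope,
                            value=float(row[col]),
                            position_from=lo,
                            position_to=hi,
                        )
                    )
    elif module == "Per sequence GC content":
        for row in rows:
            records.append(
                MetricRecord(
                    key=key,
                    name=f"gc_content_{row[0]}",
                    scope="run",
                    value=float(row[1]),
                )
            )
    else:
        # Unknown modules: keep row conservation with generic run-scope rows.
        for row in rows:
            records.append(
                MetricRecord(
                    key=key,
                    name=f"{slug}_{row[0].lower().replace(' ', '_')}",
                    scope="run",
                    value=_maybe_number(row[1]) if len(row) > 1 else "",
                )
            )
    return records


def parse_toolkit_reports(reports: Iterable[str | dict], key: RunKey) -> list[MetricRecord]:
    """Flatten this toolkit's JSON reports into metric records.

    Scalars become run-scope records named <report_type>_<field>;
    histograms keyed by integer (multiplicity, cycle, GC bin) become
    base-scope series.  Scalar values survive losslessly.
    """
    records: list[MetricRecord] = []
    for report in reports:
        data = json.loads(report) if isinstance(report, str) else report
        if isinstance(data, list):
            records.extend(parse_toolkit_reports(data, key))
            continue
        rtype = data.get("report_type")
        if rtype is None:
            raise ValueError("unknown report type: missing 'report_type' field")
        for field_name, value in data.items():
            if field_name == "report_type":
                continue
            records.extend(_flatten_field(rtype, field_name, value, key))
    return records


def _flatten_field(rtype: str, field_name: str, value: Any, key: RunKey) -> list[MetricRecord]:
    name = f"{rtype}_{field_name}"
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return [MetricRecord(key=key, name=name, scope="run", value=value)]
    if isinstance(value, str):
        return [MetricRecord(key=key, name=name, scope="run", value=value)]
    if isinstance(value, dict):
        records = []
        for sub_key, sub_value in value.items():
            try:
                pos = int(sub_key)
            except (TypeError, ValueError):
                if isinstance(sub_value, (int, float, str)):
                    records.append(
                        MetricRecord(
                            key=key, name=f"{name}_{sub_key}", scope="run", value=sub_value
                        )
                    )
                continue
            if isinstance(sub_value, (int, float)) and pos >= 1:
                records.append(
                    MetricRecord(
                        key=key,
                        name=name,
                        scope="base",
                        value=sub_value,
                        position_from=pos,
                        position_to=pos,
                    )
                )
        return records
    return []
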