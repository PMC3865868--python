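"""Pipeline configuration: a flat YAML key-value file with CLI overrides.

Defaults follow routine screening practice: k=21 for contamination
screening with 10% subsampling, k=31 for spectra, a minimum clipped read
length of 25 and the standard 38-base Nextera junction adaptor.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import yaml

from knowyourdata.matepair import AdaptorSpec, NEXTERA_JUNCTION


@dataclass
class PipelineConfig:
    k_screen: int = 21
    k_spectra: int = 31
    subsample_fraction: float = 0.10
    subsample_mode: str = "systematic"
    junction_sequence: str = NEXTERA_JUNCTION
    junction_min_overlap: int = 18
    junction_max_mismatch_rate: float = 4 / 38
    min_length: int = 25
    read_hit_threshold_pct: float = 5.0
    coverage_threshold_pct: float = 20.0
    smoothing_window: int = 5
    het_tolerance: float = 0.25
    thresholds: dict[str, float] = field(default_factory=dict)
    store_path: str = "kyd_metrics.sqlite"
    seed: int = 0

    def adaptor_spec(self) -> AdaptorSpec:
        return AdaptorSpec(
            junction_sequence=self.junction_sequence,
            min_overlap=self.junction_min_overlap,
            max_mismatch_rate=self.junction_max_mismatch_rate,
        )

    def to_yaml(self, path: str | os.PathLike) -> str:
        path = os.fspath(path)
        with open(path, "wt") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)
        return path


def load_config(path: str | os.PathLike | None = None, **overrides) -> PipelineConfig:
    """Config from YAML (if given), with keyword overrides taking precedence."""
    values: dict = {}
    if path is not None:
        with open(os.fspath(path), "rt") as handle:
            loaded = yaml.safe_load(handle) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = set(PipelineConfig.__dataclass_fields__)
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)
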