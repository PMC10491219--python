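"""Run configuration: one YAML file drives the whole pipeline.

A single global ``seed`` fans out to per-stage streams by stable integer
offsets, so any stage can be rerun in isolation with the stream it would
have received in a full run.  Validation reports unknown keys as warnings
(forward compatibility) and out-of-range values or missing files as errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, asdict
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    pass


#: Stable per-stage offsets added to the global seed.
STAGE_SEED_OFFSETS = {
    "simulate": 11, "correct": 23, "downsample": 37,
    "graph": 53, "transfer": 71, "stats": 89,
}


def stage_seed(global_seed: int, stage: str) -> int:
    if stage not in STAGE_SEED_OFFSETS:
        raise ConfigError(f"unknown stage {stage!r}")
    return (int(global_seed) + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class SimulateConfig:
    enabled: bool = True
    n_events_per_sample: int = 1500
    n_batches: int = 3
    tissues: list[str] = field(default_factory=lambda: ["BM", "mPB"])
    samples_per_tissue_per_batch: int = 1
    noise_sd: float | None = None
    zero_inflation: float | None = None


@dataclass
class PreprocessConfig:
    cofactor: float = 5.0
    scale_percentile: float = 99.9
    apply_gates: bool = True


@dataclass
class CorrectConfig:
    enabled: bool = True
    percentile: float = 99.8


@dataclass
class DownsampleConfig:
    enabled: bool = False
    total_n: int = 0
    group_keys: list[str] = field(default_factory=lambda: ["tissue", "sample_id"])


@dataclass
class GraphConfig:
    k: int = 15
    m: int = 15
    resolution: float = 4.0
    edge_threshold: float = 0.1
    population_edge_threshold: float = 0.002
    root_population: str = "HSC"
    pseudotime_method: str = "diffusion"


@dataclass
class TransferConfig:
    enabled: bool = True
    reference_tissue: str = "BM"
    k: int = 15
    min_ref: int | None = None


@dataclass
class StatsConfig:
    n_bins: int = 200
    smoothing_window: int = 9
    linkage: str = "average"
    positivity_percentile: float = 95.0


@dataclass
class PathsConfig:
    output_dir: str = "runs/demo"
    fcs_dir: str | None = None        # required when simulate.enabled is false
    metadata: str | None = None
    annotation: str | None = None     # metacluster map YAML (else truth-derived)


@dataclass
class RunConfig:
    seed: int = 0
    paths: PathsConfig = field(default_factory=PathsConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    correct: CorrectConfig = field(default_factory=CorrectConfig)
    downsample: DownsampleConfig = field(default_factory=DownsampleConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    transfer: TransferConfig = field(default_factory=TransferConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "paths": PathsConfig, "simulate": SimulateConfig,
    "preprocess": PreprocessConfig, "correct": CorrectConfig,
    "downsample": DownsampleConfig, "graph": GraphConfig,
    "transfer": TransferConfig, "stats": StatsConfig,
}


def _build_section(cls, payload: dict, section: str, warnings: list[str]):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(payload) - known
    if unknown:
        warnings.append(f"{section}: unknown keys ignored: {sorted(unknown)}")
    return cls(**{k: v for k, v in payload.items() if k in known})


def load_config(path: str | Path) -> tuple[RunConfig, list[str]]:
    """Parse a YAML config; returns (config, warnings). Raises on bad YAML."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ConfigError("config root must be a mapping")
    warnings: list[str] = []
    kwargs = {}
    top_known = {"seed"} | set(_SECTIONS)
    unknown_top = set(payload) - top_known
    if unknown_top:
        warnings.append(f"top level: unknown keys ignored: {sorted(unknown_top)}")
    kwargs["seed"] = int(payload.get("seed", 0))
    for section, cls in _SECTIONS.items():
        sub = payload.get(section, {}) or {}
        if not isinstance(sub, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        kwargs[section] = _build_section(cls, sub, section, warnings)
    return RunConfig(**kwargs), warnings


def validate_config(config: RunConfig) -> list[str]:
    """Range/consistency/file checks; returns a list of error strings."""
    errors: list[str] = []
    c = config
    if c.preprocess.cofactor <= 0:
        errors.append("preprocess.cofactor must be > 0")
    if not (0 < c.preprocess.scale_percentile < 100):
        errors.append("preprocess.scale_percentile must be in (0, 100)")
    if not (0 < c.correct.percentile < 100):
        errors.append("correct.percentile must be in (0, 100)")
    if c.graph.k < 1:
        errors.append("graph.k must be >= 1")
    if c.graph.m < 1:
        errors.append("graph.m must be >= 1")
    if c.graph.resolution <= 0:
        errors.append("graph.resolution must be > 0")
    if c.graph.pseudotime_method not in ("diffusion", "geodesic"):
        errors.append("graph.pseudotime_method must be diffusion or geodesic")
    if c.stats.n_bins < 2:
        errors.append("stats.n_bins must be >= 2")
    if c.stats.smoothing_window % 2 == 0 or c.stats.smoothing_window < 1:
        errors.append("stats.smoothing_window must be a positive odd number")
    if c.downsample.enabled and c.downsample.total_n <= 0:
        errors.append("downsample.total_n must be > 0 when downsampling")
    if c.transfer.enabled and c.transfer.k < 1:
        errors.append("transfer.k must be >= 1")
    if c.simulate.enabled:
        if c.simulate.n_events_per_sample <= 0:
            errors.append("simulate.n_events_per_sample must be > 0")
        if c.simulate.n_batches < 1:
            errors.append("simulate.n_batches must be >= 1")
    else:
        for key in ("fcs_dir", "metadata"):
            val = getattr(c.paths, key)
            if not val:
                errors.append(f"paths.{key} is required when simulate is disabled")
            elif not Path(val).exists():
                errors.append(f"paths.{key}: no such path {val!r}")
    if c.paths.annotation and not Path(c.paths.annotation).exists():
        errors.append(f"paths.annotation: no such file {c.paths.annotation!r}")
    return errors
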