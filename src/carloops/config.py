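"""Structured, versioned run configuration.

A serialized config fully reproduces a run: same config + seed means
identical outputs.  Unknown keys are errors, not warnings.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .residency import SCENARIO_NAMES

SCHEMA_VERSION = 1


@dataclass
class GenomeConfig:
    chrom_name: str = "chrS"
    chrom_length: int = 750_000
    n_cars: int = 90
    spacing_median: float = 8_000.0
    spacing_sigma: float = 0.45
    occupancy_distribution: str = "residency-mixture"  # or "beta"
    occupancy_a: float = 2.0
    occupancy_b: float = 2.0
    centromere: int = 375_000
    chip_depth: float = 2.0
    chip_peak_width: float = 1_000.0
    chip_peak_gain: float = 1_000.0
    chip_bin_size: int = 100
    high_residency_fraction: float = 0.10


@dataclass
class SimulationConfig:
    n_cells: int = 3_000
    mode: str = "consecutive"          # or "extruder"
    processivity: float = 50_000.0
    n_extruders: int = 0               # 0 -> one per 30 kb


@dataclass
class RenderConfig:
    bin_size: int = 200
    alpha: float = 1.0
    s0: float = 1_000.0
    focal_weight: float = 0.002
    domain_weight: float = 0.3
    anchor_sigma: float = 500.0
    total_reads: float = 20_000_000.0
    noise: bool = True


@dataclass
class AnalysisConfig:
    loop_min_dist: int = 5_000
    loop_max_dist: int = 100_000
    loop_fold_min: float = 2.0
    loop_fdr: float = 0.1
    donut_inner: int = 2
    donut_outer: int = 5
    pileup_half_width: int = 5_000
    corner_size: int = 14
    max_interval_k: int = 10
    insulation_res: int = 2_000
    insulation_window: int = 15_000
    boundary_prominence: float = 0.4
    decay_slope_window: int = 5
    ada_pseudo_size: int = 30


@dataclass
class RunConfig:
    scenario: str = "WT"
    seed: int = 0
    outdir: str = "results/run"
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self):
        if self.scenario.upper() not in SCENARIO_NAMES:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        self.scenario = self.scenario.upper()

    def to_yaml(self, path) -> None:
        doc = {"schema_version": SCHEMA_VERSION, **asdict(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        version = doc.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"{path}: schema_version {version!r}, expected {SCHEMA_VERSION}")
        return cls.from_dict(doc, source=str(path))

    @classmethod
    def from_dict(cls, doc: dict, source: str = "<dict>") -> "RunConfig":
        sections = {"genome": GenomeConfig, "simulation": SimulationConfig,
                    "render": RenderConfig, "analysis": AnalysisConfig}
        kwargs = {}
        top_known = {f.name for f in fields(cls)}
        for key, value in doc.items():
            if key not in top_known:
                raise ConfigError(f"{source}: unknown config key {key!r}")
            if key in sections:
                sub_cls = sections[key]
                known = {f.name for f in fields(sub_cls)}
                unknown = set(value) - known
                if unknown:
                    raise ConfigError(f"{source}: unknown {key} keys {sorted(unknown)}")
                kwargs[key] = sub_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)
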