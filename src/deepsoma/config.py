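"""Plain-text (YAML) pipeline configuration."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .filters import DEFAULT_ALPHA_GRID, FilterThresholds


@dataclass
class PipelineConfig:
    """Every knob of the simulate -> noise -> filter -> report pipeline.

    Simulation defaults emulate the study conditions this pipeline targets:
    2000-3500x depth, log-uniform clone VAFs concentrated below 1%, CpG C>T
    noise an order of magnitude above the base substitution rate, and an
    age-linear clone burden averaging ~15 clones per 35-year-old subject.
    The default panel is scaled down from the ~2500-gene / 5 Mb design to
    keep a desk-scale run fast; panel_n_genes and mean_gene_length scale it.
    """

    # cohort
    n_cases: int = 4
    n_controls: int = 4
    depth_lo: float = 1460.0
    depth_hi: float = 3534.0
    # panel (used when no panel_bed is given)
    panel_n_genes: int = 40
    mean_gene_length: int = 2000
    cpg_fraction: float = 0.04
    # noise and clones
    noise_base_rate: float = 1e-4
    cpg_ct_multiplier: float = 10.0
    burden_slope: float = 0.443
    vaf_min: float = 0.002
    vaf_max: float = 0.09
    # caller emulation / annotation shape
    candidate_min_alt: int = 3
    expressed_fraction: float = 0.8
    pop_site_density: float = 1.0 / 750.0
    include_germline_in_candidates: bool = False
    # filtering
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    pooled_noise: bool = False
    calibrate: bool = True
    # optional external inputs
    panel_bed: str | None = None
    expressed_genes_path: str | None = None
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["thresholds"] = dataclasses.asdict(self.thresholds)
        data["alpha_grid"] = list(self.alpha_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "thresholds" in data and isinstance(data["thresholds"], dict):
            data["thresholds"] = FilterThresholds(**data["thresholds"])
        if "alpha_grid" in data:
            data["alpha_grid"] = tuple(float(a) for a in data["alpha_grid"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
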