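"""Pipeline configuration: every analysis threshold in one place.

Defaults reproduce the analysis constants of the study design exactly
(r_min = 0.75, alpha = 0.05, SNR > 3, >= 6 cells at <= 533 um^2/cell,
3/5-frame windows, 1.8 Hz imaging, 60 Hz eye tracking); any override is
recorded in the run report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .assemblies import AssemblyParams
from .behavior import DetectorParams
from .synthdata.eyes import BehaviorParams
from .synthdata.fluorescence import NoiseParams
from .synthdata.population import DEFAULT_MIXTURE, GeometryParams


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "preyscope_out"

    # simulation scale
    n_planes: int = 1
    reps: int = 5
    n_rois: int = 300
    n_fish: int = 8
    mixture_weights: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))

    # analysis thresholds
    r_min: float = 0.75
    min_fish: int = 6
    min_cluster_cells: int = 6
    alpha: float = 0.05
    snr_min: float = 3.0
    assembly_min_cells: int = 6
    assembly_max_density: float = 533.0
    n_perm: int = 5
    n_splits: int = 10

    # optional real-data inputs (bypass simulation)
    schedule_csv: Optional[str] = None
    eyes_csv: Optional[str] = None
    trace_store: Optional[str] = None
    rois_csv: Optional[str] = None

    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    detector: DetectorParams = field(default_factory=DetectorParams)
    noise: NoiseParams = field(default_factory=NoiseParams)

    def geometry(self) -> GeometryParams:
        return GeometryParams(n_rois=self.n_rois, n_fish=self.n_fish)

    def assembly_params(self) -> AssemblyParams:
        return AssemblyParams(
            alpha=self.alpha,
            snr_min=self.snr_min,
            min_cells=self.assembly_min_cells,
            max_density_um2=self.assembly_max_density,
        )

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        nested = {"behavior": BehaviorParams, "detector": DetectorParams,
                  "noise": NoiseParams}
        for k, v in raw.items():
            if k in nested:
                kwargs[k] = nested[k](**v)
            elif k in {f.name for f in dataclasses.fields(cls)}:
                kwargs[k] = v
            else:
                raise ConfigError(f"unknown configuration field '{k}'")
        return cls(**kwargs)
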