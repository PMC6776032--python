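"""Pipeline configuration with documented defaults.

Every numeric default is either the published constant for the method
(marker bands 1170/1726/481 cm⁻¹, calibration coefficients, loss
fractions 12%/8%, sixth-order baseline) or a documented convention
(despike threshold, LOD rule, synthetic-data parameters). A YAML file
overrides any subset; CLI flags override the file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cellquant import DEFAULT_LOSS_FRACTIONS
from .plants import DEFAULT_ASSIMILATED_P, DEFAULT_BIOVOLUME_PER_GSS
from .spectra import ANALYTES

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # preprocessing
    baseline_order: int = 6
    despike_z_threshold: float = 8.0
    # analytes: name -> calibration coefficient (g um^-2 count^-1)
    k: dict = field(default_factory=lambda: {n: a.k for n, a in ANALYTES.items()})
    loss: dict = field(default_factory=lambda: dict(DEFAULT_LOSS_FRACTIONS))
    lod_multiplier: float = 3.0
    band_mode: str = "height"
    # droplet calibration
    segmentation_threshold: float = 0.05
    whole_map_n: bool = False
    # synthetic scenario
    droplet_mass_g: float = 5.0e-8
    droplet_area_um2: float = 324473.0
    pixel_area_um2: float = 225.0
    n_cells: int = 100
    cell_mass_mean_g: float = 1.1e-13
    cell_mass_sd_g: float = 0.5e-13
    cell_area_um2: float = 3.79
    noise_sd: float = 1.0  # ~1% of a typical cell marker band (SNR ~100)
    cosmic_rate: float = 0.0
    # plant accounting
    biovolume_per_gss: float = DEFAULT_BIOVOLUME_PER_GSS
    assimilated_p: float = DEFAULT_ASSIMILATED_P

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = PipelineConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
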